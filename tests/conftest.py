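import numpy as np
import pytest

from oildrop import (
    HydroScale,
    ResidueRecord,
    SyntheticSpec,
    build_profile,
    generate_structure,
)

#: minimal hand-written PDB fragment: GLY-ALA-LEU with full heavy atoms
THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   5       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   5       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   5       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   5       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   6       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   6       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   ALA A   6       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   ALA A   6       6.030   1.580   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   6       3.543   3.658   1.207  1.00  0.00           C
ATOM     10  N   LEU A   7       6.201   3.823   0.000  1.00  0.00           N
ATOM     11  CA  LEU A   7       7.657   3.846   0.000  1.00  0.00           C
ATOM     12  C   LEU A   7       8.215   5.262   0.000  1.00  0.00           C
ATOM     13  O   LEU A   7       7.460   6.232   0.000  1.00  0.00           O
ATOM     14  CB  LEU A   7       8.187   3.080   1.217  1.00  0.00           C
ATOM     15  CG  LEU A   7       9.707   2.906   1.276  1.00  0.00           C
ATOM     16  CD1 LEU A   7      10.175   2.123   2.497  1.00  0.00           C
ATOM     17  CD2 LEU A   7      10.406   4.259   1.272  1.00  0.00           C
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A 102       3.000   0.000   0.000  1.00  0.00           O
HETATM    3 CU    CU A 201       5.000   5.000   5.000  1.00  0.00          CU
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "tripeptide.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


@pytest.fixture
def flat_scale():
    """All residues share intrinsic hydrophobicity 0.5, GLY pinned at 0."""
    from oildrop.scales import STANDARD_AA3

    values = {aa: 0.5 for aa in STANDARD_AA3}
    values["GLY"] = 0.0
    return HydroScale("flat", values, {"MSE": "MET"})


def random_records(n: int, seed: int, box: float = 20.0) -> list[ResidueRecord]:
    """Random residue cloud with random non-negative hydrophobicity."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(-box / 2, box / 2, size=(n, 3))
    h = rng.uniform(0.0, 1.0, size=n)
    return [
        ResidueRecord("A", i + 1, "", "ALA", tuple(xyz[i]), float(h[i]))
        for i in range(n)
    ]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def micelle_profile():
    records, _ = generate_structure(SyntheticSpec(n_residues=60, seed=7))
    return build_profile(records)
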