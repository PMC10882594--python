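"""Structure input: effective atoms, hydrophobicity assignment, selections.

Each amino-acid residue is reduced to a single *effective atom* — the
unweighted arithmetic mean of its heavy-atom coordinates — at which all
hydrophobicity fields are evaluated.  Parsing is delegated to Bio.PDB
(PDB and mmCIF); HETATM groups, waters, ions and cofactors are excluded,
except nonstandard residues with a registered alias (e.g. MSE -> MET).

Residue identity uses author numbering plus insertion code, because
catalytic residues and domain ranges are conventionally quoted in author
numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .scales import DEFAULT_ALIASES, HydroScale, get_scale

__all__ = [
    "ResidueRecord",
    "UnitSelection",
    "StructureError",
    "parse_structure",
    "effective_atom",
    "assign_hydrophobicity",
    "resolve_selection",
    "write_selection_tsv",
    "read_selection_tsv",
]

logger = logging.getLogger(__name__)

STANDARD_SET = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)


class StructureError(ValueError):
    """Unreadable, empty, or inconsistently selected structure."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to its effective atom.

    ``intrinsic_h`` is the dimensionless intrinsic hydrophobicity Hir,
    NaN until a scale has been assigned.
    """

    chain_id: str
    auth_seq_id: int
    insertion_code: str
    aa3: str
    effective_xyz: tuple[float, float, float]
    intrinsic_h: float = float("nan")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_id, self.insertion_code)

    def label(self) -> str:
        return f"{self.chain_id}:{self.auth_seq_id}{self.insertion_code}"


@dataclass(frozen=True)
class UnitSelection:
    """Declarative description of a structural unit.

    ``mode`` distinguishes a fragment analysed with its own fitted
    Gaussian (``individual``) from one inheriting the parent unit's
    field and renormalized over the fragment (``part_of_parent``).
    Ranges are inclusive and in author numbering.
    """

    name: str = "all"
    chains: tuple[str, ...] = ()
    ranges: tuple[tuple[str, int, int], ...] = ()
    excluded: tuple[tuple[str, int, str], ...] = ()
    mode: str = "individual"

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "part_of_parent"):
            raise ValueError(f"invalid mode {self.mode!r}")


def effective_atom(residue_heavy_atoms: Sequence) -> np.ndarray:
    """Unweighted arithmetic mean of a residue's heavy-atom coordinates."""
    coords = np.asarray(residue_heavy_atoms, dtype=float)
    if coords.size == 0:
        raise StructureError("residue has no heavy atoms")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise StructureError(f"expected (n, 3) coordinates, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise StructureError("non-finite atom coordinates")
    return coords.mean(axis=0)


def _residue_records_from_model(model, aliases: dict[str, str]) -> list[ResidueRecord]:
    records: list[ResidueRecord] = []
    for chain in model:
        for residue in chain:
            hetfield, resseq, icode = residue.id
            resname = residue.get_resname().strip().upper()
            if resname not in STANDARD_SET and resname not in aliases:
                continue  # waters, ions, cofactors, ligands
            if hetfield.startswith("W"):
                continue
            coords = [
                atom.get_coord()
                for atom in residue.get_atoms()  # DisorderedAtom yields the
                if atom.element != "H"           # highest-occupancy conformer
            ]
            if not coords:
                logger.warning(
                    "skipping residue %s %s%s: no heavy atoms",
                    resname, resseq, icode.strip(),
                )
                continue
            records.append(
                ResidueRecord(
                    chain_id=chain.id,
                    auth_seq_id=int(resseq),
                    insertion_code=icode.strip(),
                    aa3=resname,
                    effective_xyz=tuple(map(float, effective_atom(coords))),
                )
            )
    return records


def parse_structure(
    path: str | Path,
    model_index: int = 0,
    aliases: dict[str, str] | None = None,
) -> list[ResidueRecord]:
    """Read a PDB or mmCIF file into per-residue effective-atom records.

    Only standard amino acids (plus aliased residues such as MSE) are
    kept; alternate locations resolve to the highest-occupancy conformer.
    Records are returned grouped by chain in file order.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises heterogeneous parse errors
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models")
    if model_index >= len(models):
        raise StructureError(
            f"{path}: model index {model_index} out of range ({len(models)} models)"
        )
    records = _residue_records_from_model(
        models[model_index], aliases if aliases is not None else dict(DEFAULT_ALIASES)
    )
    if not records:
        raise StructureError(f"{path}: no standard amino-acid residues found")
    _check_unique(records)
    return records


def _check_unique(records: Sequence[ResidueRecord]) -> None:
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise StructureError(f"duplicate residue identifier {rec.label()}")
        seen.add(rec.key)


def assign_hydrophobicity(
    records: Sequence[ResidueRecord],
    scale: HydroScale | str = "aggregate",
) -> list[ResidueRecord]:
    """Attach intrinsic hydrophobicity from *scale*, preserving order."""
    if isinstance(scale, str):
        scale = get_scale(scale)
    out: list[ResidueRecord] = []
    for pos, rec in enumerate(records):
        if rec.aa3 not in scale:
            raise KeyError(
                f"unknown residue code {rec.aa3!r} at position {pos} "
                f"({rec.label()}) for scale {scale.name!r}"
            )
        out.append(replace(rec, intrinsic_h=scale[rec.aa3]))
    return out


def resolve_selection(
    records: Sequence[ResidueRecord],
    selection: UnitSelection,
) -> list[ResidueRecord]:
    """Resolve a declarative selection into an ordered, duplicate-free
    residue list.

    A record is selected if it matches any listed chain or any inclusive
    author-numbered range, then pruned of explicitly excluded residues.
    An empty ``chains``+``ranges`` pair selects everything.
    """
    excluded = {(c, s, i) for (c, s, i) in selection.excluded}

    def wanted(rec: ResidueRecord) -> bool:
        if rec.key in excluded:
            return False
        if not selection.chains and not selection.ranges:
            return True
        if rec.chain_id in selection.chains:
            return True
        return any(
            rec.chain_id == c and lo <= rec.auth_seq_id <= hi
            for (c, lo, hi) in selection.ranges
        )

    out = [rec for rec in records if wanted(rec)]
    if not out:
        raise StructureError(f"selection {selection.name!r} resolves to no residues")
    missing = excluded - {rec.key for rec in records}
    if missing:
        raise StructureError(
            f"excluded residues not present in structure: {sorted(missing)}"
        )
    return out


_TSV_HEADER = "chain\tauth_seq_id\ticode\taa3\tx\ty\tz\tintrinsic_h"


def write_selection_tsv(records: Iterable[ResidueRecord], path: str | Path) -> None:
    lines = [_TSV_HEADER]
    for rec in records:
        x, y, z = rec.effective_xyz
        lines.append(
            f"{rec.chain_id}\t{rec.auth_seq_id}\t{rec.insertion_code}\t{rec.aa3}"
            f"\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{rec.intrinsic_h:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_selection_tsv(path: str | Path) -> list[ResidueRecord]:
    """Round-trip reader for :func:`write_selection_tsv` output.

    Also the reader for effective-atom tables prepared offline from
    full structure files.
    """
    records: list[ResidueRecord] = []
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("chain\t"):
        raise StructureError(f"{path}: missing selection TSV header")
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise StructureError(f"{path}:{lineno}: expected 8 columns")
        chain, seq, icode, aa3, x, y, z, h = parts
        records.append(
            ResidueRecord(
                chain_id=chain,
                auth_seq_id=int(seq),
                insertion_code=icode,
                aa3=aa3,
                effective_xyz=(float(x), float(y), float(z)),
                intrinsic_h=float(h),
            )
        )
    if not records:
        raise StructureError(f"{path}: empty selection table")
    _check_unique(records)
    return records
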