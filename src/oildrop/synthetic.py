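"""Synthetic structures and profiles with known hydrophobicity ground truth.

These generators make every stage of the pipeline testable without any
structure download.  They encode hydrophobicity *geometry* only — no
physics, no chains of bonded residues — in four organizations mirroring
the environments a folding chain can experience:

``micelle``          aqueous folding: hydrophobic residues buried near
                     the centroid, polar residues outside (low RD, low K);
``inverse_micelle``  nonpolar environment: hydrophilic core, hydrophobic
                     surface (high RD, high K);
``random``           mixed environment: hydrophobicity uncorrelated with
                     position;
``polarized``        phase-separated environment: hydrophobic residues on
                     one side of a plane.

Residues are written as standard amino acids chosen to carry the desired
intrinsic hydrophobicity under the active scale, so synthetic files pass
through the ordinary parsing and assignment path unchanged.  Coordinates
are placed at protein-like packing density (~120 Å³ per residue).
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import HydroProfile, fit_gaussian_frame, theoretical_profile
from .fodm import m_profile
from .io import ResidueRecord, UnitSelection
from .scales import HydroScale, get_scale

__all__ = [
    "SyntheticSpec",
    "generate_structure",
    "generate_profile_with_known_k",
    "write_pdb",
    "write_truth_tsv",
]

GEOMETRIES = ("ellipsoid_cloud", "shell", "helix", "two_domain")
ORGANIZATIONS = ("micelle", "inverse_micelle", "random", "polarized")

#: Approximate volume per residue in a packed globule, Å^3.
RESIDUE_VOLUME = 120.0
#: Ellipsoid axis anisotropy of the synthetic body.
AXIS_RATIOS = np.array([1.3, 1.0, 0.8])


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic structure."""

    n_residues: int = 60
    geometry: str = "ellipsoid_cloud"
    organization: str = "micelle"
    seed: int = 0
    noise_sigma: float = 0.0
    strength: float = 1.0  # 0 = fully random identity, 1 = fully graded

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.organization not in ORGANIZATIONS:
            raise ValueError(f"organization must be one of {ORGANIZATIONS}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _body_radius(n: int) -> float:
    # (4/3) pi (a b c) R^3 = n * RESIDUE_VOLUME with (a,b,c) = AXIS_RATIOS * R
    abc = float(np.prod(AXIS_RATIOS))
    return (3.0 * n * RESIDUE_VOLUME / (4.0 * np.pi * abc)) ** (1.0 / 3.0)


def _sample_coords(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    R = _body_radius(n)
    semi = AXIS_RATIOS * R

    def ball(m: int) -> np.ndarray:
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(size=(m, 1)) ** (1.0 / 3.0)
        return v * r

    if spec.geometry == "ellipsoid_cloud":
        xyz = ball(n) * semi
    elif spec.geometry == "shell":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(0.85, 1.0, size=(n, 1))
        xyz = v * r * semi
    elif spec.geometry == "helix":
        # alpha-helix-like rod: 2.3 A radius, 1.5 A rise, 100 deg per residue
        i = np.arange(n)
        theta = np.deg2rad(100.0) * i
        xyz = np.column_stack(
            [1.5 * (i - (n - 1) / 2), 2.3 * np.cos(theta), 2.3 * np.sin(theta)]
        )
    else:  # two_domain
        n1 = n // 2
        semi_d = AXIS_RATIOS * _body_radius(max(n1, n - n1))
        offset = np.array([1.4 * semi_d[0], 0.0, 0.0])
        xyz = np.vstack(
            [ball(n1) * semi_d - offset, ball(n - n1) * semi_d + offset]
        )
    if spec.noise_sigma > 0:
        xyz = xyz + rng.normal(scale=spec.noise_sigma, size=xyz.shape)
    return xyz


def _target_hydrophobicity(
    spec: SyntheticSpec, xyz: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-residue target intrinsic hydrophobicity in [0, 1].

    The micelle target follows the same three-sigma Gaussian decay that
    the theoretical field assumes (exp(-9/2 · d²) with d the fractional
    ellipsoidal radius), so a fully organized micelle carries intrinsic
    hydrophobicity shaped like the ideal field; the inverse micelle is
    its complement.  ``strength`` blends the ideal target with uniform
    noise.
    """
    n = len(xyz)
    center = xyz.mean(axis=0)
    centered = xyz - center
    scale = np.maximum(np.abs(centered).max(axis=0), 1e-9)
    d = np.linalg.norm(centered / scale, axis=1)
    d = d / max(d.max(), 1e-9)  # 0 at the centroid, 1 at the surface

    if spec.organization == "micelle":
        ideal = np.exp(-4.5 * d**2)
    elif spec.organization == "inverse_micelle":
        ideal = 1.0 - np.exp(-4.5 * d**2)
    elif spec.organization == "polarized":
        x = centered[:, 0]
        ideal = np.empty(n)
        ideal[np.argsort(x)] = np.linspace(0.0, 1.0, n)
    else:  # random
        ideal = rng.uniform(size=n)

    noise = rng.uniform(size=n)
    return spec.strength * ideal + (1.0 - spec.strength) * noise


def generate_structure(
    spec: SyntheticSpec,
    scale: HydroScale | str = "aggregate",
) -> tuple[list[ResidueRecord], dict]:
    """Generate one synthetic structure.

    Returns the residue records (hydrophobicity already assigned from
    *scale*) and a ground-truth dict with the spec, per-residue target
    quantiles, and coordinates.
    """
    if isinstance(scale, str):
        scale = get_scale(scale)
    rng = np.random.default_rng(spec.seed)
    xyz = _sample_coords(spec, rng)
    target = _target_hydrophobicity(spec, xyz, rng)

    # nearest-value assignment: pick the residue type whose intrinsic
    # hydrophobicity under the active scale is closest to the target
    by_h = sorted((aa for aa in scale.values), key=lambda aa: scale.values[aa])
    ladder = np.array([scale.values[aa] for aa in by_h])
    idx = np.abs(ladder[None, :] - target[:, None]).argmin(axis=1)

    records = [
        ResidueRecord(
            chain_id="A",
            auth_seq_id=i + 1,
            insertion_code="",
            aa3=by_h[idx[i]],
            effective_xyz=tuple(np.round(xyz[i], 3)),
            intrinsic_h=scale[by_h[idx[i]]],
        )
        for i in range(spec.n_residues)
    ]
    truth = {
        "spec": spec,
        "target_h": target,
        "xyz": xyz,
        "scale": scale.name,
    }
    return records, truth


def write_pdb(records: Sequence[ResidueRecord], path: str | Path) -> None:
    """Write one CA pseudo-atom per residue at the effective position.

    The file is a valid single-model PDB readable by the ordinary
    structure parser.
    """
    lines = []
    for serial, rec in enumerate(records, 1):
        x, y, z = rec.effective_xyz
        lines.append(
            f"ATOM  {serial:>5d}  CA  {rec.aa3:<3s} {rec.chain_id}"
            f"{rec.auth_seq_id:>4d}{rec.insertion_code or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(truth: dict, path: str | Path) -> None:
    spec: SyntheticSpec = truth["spec"]
    lines = [
        f"# geometry={spec.geometry} organization={spec.organization} "
        f"seed={spec.seed} strength={spec.strength} scale={truth['scale']}",
        "index\ttarget_h\tx\ty\tz",
    ]
    for i, (q, p) in enumerate(zip(truth["target_h"], truth["xyz"])):
        lines.append(f"{i}\t{q:.6f}\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_profile_with_known_k(
    n: int,
    k_true: float,
    seed: int = 0,
    noise: float = 0.0,
) -> HydroProfile:
    """Profile whose observed distribution is exactly M(T, k_true).

    A random cloud supplies a valid fitted T; O is constructed as the
    environment-modified field at *k_true*, optionally perturbed by a
    multiplicative noise of relative magnitude *noise* and renormalized.
    K-scan recovery of *k_true* is then generator-known truth.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(n_residues=max(n, 10), geometry="ellipsoid_cloud",
                         organization="random", seed=int(rng.integers(2**31)))
    xyz = _sample_coords(spec, rng)[:n]
    frame = fit_gaussian_frame(xyz)
    records = [
        ResidueRecord("A", i + 1, "", "ALA", tuple(xyz[i]), 0.5)
        for i in range(n)
    ]
    raw_T, T = theoretical_profile(records, frame)
    O = m_profile(T, k_true)
    if noise > 0:
        factor = np.clip(1.0 + noise * rng.standard_normal(n), 0.05, None)
        O = O * factor
        O = O / O.sum()
    return HydroProfile(
        unit=UnitSelection(name=f"synthetic_k{k_true:g}"),
        residues=tuple(r.key for r in records),
        raw_T=raw_T,
        raw_O=O,
        frame=frame,
        records=tuple(records),
    )
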