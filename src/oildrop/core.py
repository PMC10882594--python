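"""Core fuzzy-oil-drop fields: the 3D Gaussian frame, the T/O/R
profiles, Kullback--Leibler divergence and the RD statistic.

The model idealizes a water-soluble globular protein as a spherical
micelle: hydrophobicity peaks at the centre of the molecular body and
vanishes at the surface.  The idealized (theoretical, T) distribution is
an anisotropic 3D Gaussian fitted to the shape of the molecule and
evaluated at each residue's effective atom.  The observed (O)
distribution collects each residue's intrinsic hydrophobicity from its
spatial neighbours through Levitt's distance-weighted interaction
function with a 9 Å cutoff.  Both are normalized to unit sum and
compared — against each other and against the uniform reference R — with
the Kullback--Leibler divergence, yielding the relative distance

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)),

so RD < 0.5 means O is closer to the micelle-like ideal than to
featureless uniformity.  RD is invariant to the divergence's log base;
bits (log2) are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import ResidueRecord, UnitSelection

__all__ = [
    "GaussianFrame",
    "HydroProfile",
    "FODResult",
    "fit_gaussian_frame",
    "theoretical_profile",
    "observed_profile",
    "levitt_weight",
    "kl_divergence",
    "rd",
    "build_profile",
    "fragment_profile",
    "eliminate_residues",
    "DEFAULT_CUTOFF",
]

#: Levitt's hydrophobic-interaction cutoff distance, Å.
DEFAULT_CUTOFF = 9.0

_NORM_TOL = 1e-9


class FrameError(ValueError):
    """Degenerate point cloud — no meaningful Gaussian body frame."""


@dataclass(frozen=True)
class GaussianFrame:
    """Oriented 3D Gaussian body of the molecule.

    ``axes`` rows are the principal axes (largest variance first),
    forming a proper rotation; ``sigma`` are the per-axis standard
    deviations chosen so the whole body lies within three sigma.
    """

    center: np.ndarray
    axes: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if np.any(self.sigma <= 0):
            raise FrameError(f"non-positive sigma: {self.sigma}")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise FrameError("axes not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise FrameError("axes form an improper rotation")

    def to_frame_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Map world coordinates into the body frame."""
        return (np.asarray(xyz, float) - self.center) @ self.axes.T


def fit_gaussian_frame(
    effective_xyz: Sequence[Sequence[float]] | np.ndarray,
    margin: float = 0.0,
) -> GaussianFrame:
    """Fit the molecular body frame to a cloud of effective atoms.

    The centre is the mean of the points; the axes are the principal
    axes of the cloud (descending variance, sign-fixed to a proper
    rotation); sigma_k = (max |projection on axis k| + margin) / 3, the
    three-sigma rule, so the entire body lies inside the 3-sigma
    ellipsoid.
    """
    pts = np.asarray(effective_xyz, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise FrameError(f"need >=3 points of dimension 3, got {pts.shape}")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T  # rows = axes, descending variance
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise FrameError("collinear or degenerate point cloud")
    # Deterministic sign convention: largest-magnitude component of each
    # axis positive; restore a proper rotation afterwards.
    for k in range(3):
        lead = axes[k, np.argmax(np.abs(axes[k]))]
        if lead < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    proj = np.abs(centered @ axes.T)
    extent = proj.max(axis=0)
    if extent[2] <= 0:  # planar cloud: give the flat axis a token width
        raise FrameError("planar point cloud — zero extent along one axis")
    sigma = (extent + margin) / 3.0
    return GaussianFrame(center=center, axes=axes, sigma=sigma)


def theoretical_profile(
    records: Sequence[ResidueRecord],
    frame: GaussianFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Idealized micelle-like hydrophobicity at each effective atom.

    Returns ``(raw_T, T)`` where ``raw_T_i = exp(-x'^2/2σx²) ·
    exp(-y'^2/2σy²) · exp(-z'^2/2σz²)`` in body-frame coordinates and
    ``T`` is raw_T normalized to unit sum.  All entries are strictly
    positive.
    """
    xyz = np.asarray([r.effective_xyz for r in records], float)
    local = frame.to_frame_coords(xyz)
    raw = np.exp(-0.5 * np.sum((local / frame.sigma) ** 2, axis=1))
    total = raw.sum()
    if total <= 0:
        raise FrameError("theoretical field vanished — frame far from points")
    return raw, raw / total


def levitt_weight(r: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Levitt's hydrophobic-interaction distance weight.

    1 - (7x² - 9x⁴ + 5x⁶ - x⁸)/2 with x = r/cutoff for r <= cutoff,
    exactly 0 beyond; smoothly decays from 1 at contact to 0 at the
    cutoff.
    """
    r = np.asarray(r, float)
    x2 = (r / cutoff) ** 2
    w = 1.0 - 0.5 * (7 * x2 - 9 * x2**2 + 5 * x2**3 - x2**4)
    return np.where(r <= cutoff, w, 0.0)


def observed_profile(
    records: Sequence[ResidueRecord],
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed hydrophobicity: each residue's neighbourhood collection.

    raw_O_i = Σ_j (Hir_i + Hir_j) · w(r_ij) over pairs within the
    cutoff, with Levitt's weight w.  The self term j = i (weight 1)
    is included by default.  Returns ``(raw_O, O)`` with O normalized
    to unit sum.
    """
    h = np.asarray([r.intrinsic_h for r in records], float)
    if np.any(~np.isfinite(h)):
        raise ValueError("intrinsic hydrophobicity not assigned for all residues")
    xyz = np.asarray([r.effective_xyz for r in records], float)
    n = len(records)
    dist = squareform(pdist(xyz)) if n > 1 else np.zeros((1, 1))
    w = levitt_weight(dist, cutoff)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    # Σ_j (h_i + h_j) w_ij = h_i Σ_j w_ij + Σ_j h_j w_ij
    raw = h * w.sum(axis=1) + w @ h
    total = raw.sum()
    if total <= 0:
        raise ValueError("observed field is identically zero under this scale")
    return raw, raw / total


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback--Leibler divergence Σ P_i log2(P_i/Q_i), in bits.

    Terms with P_i = 0 contribute 0; Q_i = 0 where P_i > 0 is undefined
    (never occurs against T or R, which are strictly positive).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {Q.shape}")
    if abs(P.sum() - 1.0) > 1e-6 or abs(Q.sum() - 1.0) > 1e-6:
        raise ValueError("distributions must be normalized to unit sum")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ZeroDivisionError("Q_i = 0 where P_i > 0: divergence undefined")
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


@dataclass(frozen=True)
class HydroProfile:
    """Aligned per-residue T/O/R profiles for one structural unit."""

    unit: UnitSelection
    residues: tuple[tuple[str, int, str], ...]
    raw_T: np.ndarray
    raw_O: np.ndarray
    frame: GaussianFrame
    records: tuple[ResidueRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw_T", np.asarray(self.raw_T, float))
        object.__setattr__(self, "raw_O", np.asarray(self.raw_O, float))
        n = len(self.residues)
        if n < 2:
            raise ValueError("a profile needs at least 2 residues")
        if len(self.raw_T) != n or len(self.raw_O) != n:
            raise ValueError("profile arrays misaligned with residue list")
        if np.any(self.raw_T <= 0) or np.any(self.raw_O < 0):
            raise ValueError("raw_T must be > 0 and raw_O >= 0 everywhere")

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def T(self) -> np.ndarray:
        return self.raw_T / self.raw_T.sum()

    @property
    def O(self) -> np.ndarray:
        return self.raw_O / self.raw_O.sum()

    @property
    def R(self) -> np.ndarray:
        return np.full(self.n, 1.0 / self.n)


@dataclass(frozen=True)
class FODResult:
    """RD and its two divergence components for one unit."""

    rd: float
    dkl_OT: float
    dkl_OR: float
    n_residues: int


def build_profile(
    records: Sequence[ResidueRecord],
    unit: UnitSelection | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    margin: float = 0.0,
    include_self: bool = True,
    frame: GaussianFrame | None = None,
) -> HydroProfile:
    """Fit the frame (unless given) and assemble T and O for *records*."""
    if unit is None:
        unit = UnitSelection(name="all")
    if frame is None:
        frame = fit_gaussian_frame([r.effective_xyz for r in records], margin=margin)
    raw_T, _ = theoretical_profile(records, frame)
    raw_O, _ = observed_profile(records, cutoff=cutoff, include_self=include_self)
    return HydroProfile(
        unit=unit,
        residues=tuple(r.key for r in records),
        raw_T=raw_T,
        raw_O=raw_O,
        frame=frame,
        records=tuple(records),
    )


def rd(profile: HydroProfile) -> FODResult:
    """The relative-distance statistic RD = D(O|T) / (D(O|T) + D(O|R))."""
    O, T, R = profile.O, profile.T, profile.R
    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, R)
    denom = d_ot + d_or
    if denom == 0:
        raise ZeroDivisionError(
            "O coincides with both T and R — RD undefined"
        )
    return FODResult(rd=d_ot / denom, dkl_OT=d_ot, dkl_OR=d_or,
                     n_residues=profile.n)


def _restrict(profile: HydroProfile, keep: np.ndarray,
              unit: UnitSelection) -> HydroProfile:
    if keep.sum() < 2:
        raise ValueError("fewer than 2 residues remain in the unit")
    return HydroProfile(
        unit=unit,
        residues=tuple(r for r, k in zip(profile.residues, keep) if k),
        raw_T=profile.raw_T[keep],
        raw_O=profile.raw_O[keep],
        frame=profile.frame,
        records=tuple(r for r, k in zip(profile.records, keep) if k)
        if profile.records else (),
    )


def fragment_profile(parent: HydroProfile, selection: UnitSelection) -> HydroProfile:
    """Status of a fragment *as part of* its parent unit.

    The parent's field (frame and raw T/O values) is kept; the raw
    arrays are restricted to the selected positions and renormalized
    over the fragment, with R = 1/n_fragment.
    """
    if selection.mode != "part_of_parent":
        raise ValueError("fragment_profile requires mode='part_of_parent'")
    excluded = set(selection.excluded)
    sel_chains = set(selection.chains)

    def in_sel(key: tuple[str, int, str]) -> bool:
        chain, seq, _ = key
        if key in excluded:
            return False
        if not selection.chains and not selection.ranges:
            return True
        if chain in sel_chains:
            return True
        return any(chain == c and lo <= seq <= hi for (c, lo, hi) in selection.ranges)

    keep = np.array([in_sel(key) for key in parent.residues])
    if not keep.any():
        raise ValueError(f"selection {selection.name!r} selects no parent residues")
    return _restrict(parent, keep, unit=selection)


def eliminate_residues(
    parent: HydroProfile,
    excluded: Sequence[tuple[str, int, str]],
) -> HydroProfile:
    """Drop the listed residues, keeping the parent's fitted field.

    Used for the No-CAT protocol: the 3D Gaussian of the complete unit
    is retained, the excluded positions are removed, and T and O are
    renormalized over the remaining residues (R = 1/(N-k)).
    """
    excluded_set = set(excluded)
    unknown = excluded_set - set(parent.residues)
    if unknown:
        raise KeyError(f"residues not in unit: {sorted(unknown)}")
    keep = np.array([key not in excluded_set for key in parent.residues])
    unit = replace(parent.unit, excluded=tuple(parent.unit.excluded)
                   + tuple(sorted(excluded_set)))
    return _restrict(parent, keep, unit=unit)
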