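"""Environment-modified hydrophobicity field (FOD-M) and the K parameter.

A purely aqueous environment drives hydrophobicity toward the
micelle-like T distribution.  Non-aqueous factors — membranes,
cofactors, a polarized local milieu — push toward the *complement*
field T_max - T_i (hydrophobicity exposed at the surface instead of
buried).  The modified field mixes the two:

    M_i(K)  ∝  T_i + K · (T_max - T_i),      M normalized to unit sum,

with K >= 0 the degree of environmental modification: K = 0 is pure
water (M = T), K >= 1 a strongly modified, membrane-like field.  K is
estimated by scanning a grid and minimizing D_KL(O | M(K)); the grid
step of 0.1 matches the one-decimal precision at which K is customarily
reported, and ties break toward smaller K (the least environmental
modification that explains the observation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HydroProfile, kl_divergence

__all__ = ["FODMResult", "m_profile", "default_k_grid", "scan_k"]


@dataclass(frozen=True)
class FODMResult:
    """Optimal environment parameter and the divergence curve behind it."""

    k_opt: float
    dkl_OM_curve: dict[float, float]
    M_opt: np.ndarray
    dkl_OM_min: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "M_opt", np.asarray(self.M_opt, float))


def m_profile(T: np.ndarray, K: float) -> np.ndarray:
    """Environment-modified distribution M(K) for a normalized T."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    T = np.asarray(T, float)
    raw = T + K * (T.max() - T)
    total = raw.sum()
    if total <= 0:
        raise ValueError("modified field vanished (degenerate T)")
    return raw / total


def default_k_grid(stop: float = 2.0, step: float = 0.1) -> np.ndarray:
    """K grid 0..stop inclusive, rounded to the grid's own precision."""
    n = int(round(stop / step))
    return np.round(np.linspace(0.0, stop, n + 1), 10)


def scan_k(
    profile: HydroProfile,
    k_grid: np.ndarray | None = None,
    auto_extend_to: float = 3.0,
) -> FODMResult:
    """Select K by minimizing D_KL(O | M(K)) over a grid.

    If the minimum lands on the upper grid boundary, the grid is
    extended once (same step) up to *auto_extend_to* with a warning;
    ties break toward smaller K.  The grid always contains K = 0, so
    D_KL(O|M(k_opt)) <= D_KL(O|T).
    """
    import warnings

    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, float)
    if k_grid.size == 0:
        raise ValueError("empty K grid")
    if np.any(k_grid < 0):
        raise ValueError("K grid must be non-negative")
    k_grid = np.unique(k_grid)

    O = profile.O
    T = profile.T

    def dkl_at(k: float) -> float:
        return kl_divergence(O, m_profile(T, k))

    curve = {float(k): dkl_at(float(k)) for k in k_grid}
    k_opt = _argmin_smallest(curve)

    if k_opt == k_grid.max() and k_grid.size > 1 and k_opt < auto_extend_to:
        step = float(np.min(np.diff(k_grid)))
        extra = np.round(
            np.arange(k_grid.max() + step, auto_extend_to + step / 2, step), 10
        )
        warnings.warn(
            f"K minimum at grid boundary {k_opt:g}; extending grid to "
            f"{auto_extend_to:g}",
            stacklevel=2,
        )
        for k in extra:
            curve[float(k)] = dkl_at(float(k))
        k_opt = _argmin_smallest(curve)

    return FODMResult(
        k_opt=k_opt,
        dkl_OM_curve=curve,
        M_opt=m_profile(T, k_opt),
        dkl_OM_min=curve[k_opt],
    )


def _argmin_smallest(curve: dict[float, float]) -> float:
    """Grid argmin; exact ties resolve to the smallest K."""
    best = min(curve.values())
    return min(k for k, v in curve.items() if v == best)
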