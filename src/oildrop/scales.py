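"""Intrinsic amino-acid hydrophobicity scales.

The observed-hydrophobicity profile collects each residue's *intrinsic*
hydrophobicity ``Hir`` from its spatial neighbourhood.  The model only
requires that ``Hir`` be non-negative, so every registered scale is
min--max normalized to the closed interval [0, 1] over the 20 standard
amino acids (the most polar residue maps to 0, the most hydrophobic to 1).

The default scale, ``"aggregate"``, is the mean of three classical
hydropathy scales (Kyte--Doolittle, Hopp--Woods with the hydrophilicity
sign inverted, and Fauchere--Pliska), each min--max normalized before
averaging, with the mean re-normalized to [0, 1].  Averaging damps the
idiosyncrasies of any single scale; reported RD and K values carry a
tolerance attributable to this choice, and a user TSV scale can be
substituted everywhere a scale name is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "HydroScale",
    "STANDARD_AA3",
    "get_scale",
    "register_scale",
    "load_scale_tsv",
    "available_scales",
]

#: The 20 standard three-letter residue codes, alphabetical.
STANDARD_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Kyte & Doolittle hydropathy index.
_KYTE_DOOLITTLE = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# Hopp & Woods hydrophilicity; sign inverted below so larger = more hydrophobic.
_HOPP_WOODS_HYDROPHILICITY = {
    "ALA": -0.5, "ARG": 3.0, "ASN": 0.2, "ASP": 3.0, "CYS": -1.0,
    "GLN": 0.2, "GLU": 3.0, "GLY": 0.0, "HIS": -0.5, "ILE": -1.8,
    "LEU": -1.8, "LYS": 3.0, "MET": -1.3, "PHE": -2.5, "PRO": 0.0,
    "SER": 0.3, "THR": -0.4, "TRP": -3.4, "TYR": -2.3, "VAL": -1.5,
}

# Fauchere & Pliska octanol/water partition scale.
_FAUCHERE_PLISKA = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}


@dataclass(frozen=True)
class HydroScale:
    """A named intrinsic-hydrophobicity lookup table.

    Values are dimensionless, non-negative, and cover all 20 standard
    residues.  ``aliases`` maps nonstandard three-letter codes onto
    standard ones (e.g. selenomethionine ``MSE`` -> ``MET``).
    """

    name: str
    values: dict[str, float]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_AA3 if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        bad = {aa: v for aa, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"scale {self.name!r} has negative values: {bad}")

    def __getitem__(self, aa3: str) -> float:
        key = aa3.upper()
        key = self.aliases.get(key, key)
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(
                f"residue code {aa3!r} not in scale {self.name!r} "
                f"(no alias defined)"
            ) from None

    def __contains__(self, aa3: str) -> bool:
        key = aa3.upper()
        return self.aliases.get(key, key) in self.values


#: Default nonstandard-residue aliases, applied to every registered scale.
DEFAULT_ALIASES = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS"}


def _minmax(values: dict[str, float]) -> dict[str, float]:
    lo = min(values.values())
    hi = max(values.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in values.items()}


def _build_aggregate() -> dict[str, float]:
    parts = [
        _minmax(_KYTE_DOOLITTLE),
        _minmax({aa: -v for aa, v in _HOPP_WOODS_HYDROPHILICITY.items()}),
        _minmax(_FAUCHERE_PLISKA),
    ]
    mean = {aa: sum(p[aa] for p in parts) / len(parts) for aa in STANDARD_AA3}
    return _minmax(mean)


_REGISTRY: dict[str, HydroScale] = {}


def register_scale(scale: HydroScale) -> None:
    _REGISTRY[scale.name] = scale


def available_scales() -> list[str]:
    return sorted(_REGISTRY)


def get_scale(name_or_path: str = "aggregate") -> HydroScale:
    """Look up a registered scale by name, or load a TSV file by path."""
    if name_or_path in _REGISTRY:
        return _REGISTRY[name_or_path]
    path = Path(name_or_path)
    if path.exists():
        return load_scale_tsv(path)
    raise KeyError(
        f"unknown scale {name_or_path!r}; registered: {available_scales()}"
    )


def load_scale_tsv(path: str | Path, name: str | None = None) -> HydroScale:
    """Load a user scale from a two-column TSV (aa3<TAB>value).

    Values are min--max normalized to [0, 1] if any are negative,
    otherwise used as given.
    """
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            aa3, raw = line.split("\t")
            values[aa3.upper()] = float(raw)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'AA3<TAB>value'") from None
    if any(v < 0 for v in values.values()):
        values = _minmax(values)
    return HydroScale(
        name=name or Path(path).stem, values=values, aliases=dict(DEFAULT_ALIASES)
    )


register_scale(
    HydroScale("aggregate", _build_aggregate(), dict(DEFAULT_ALIASES))
)
register_scale(
    HydroScale("kyte_doolittle", _minmax(_KYTE_DOOLITTLE), dict(DEFAULT_ALIASES))
)
register_scale(
    HydroScale("fauchere_pliska", _minmax(_FAUCHERE_PLISKA), dict(DEFAULT_ALIASES))
)
register_scale(
    HydroScale(
        "hopp_woods_inverted",
        _minmax({aa: -v for aa, v in _HOPP_WOODS_HYDROPHILICITY.items()}),
        dict(DEFAULT_ALIASES),
    )
)
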