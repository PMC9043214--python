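"""Vole-thermometer July temperature reconstruction.

Each vole species present in a stratigraphic assemblage carries a modern
July-temperature optimum; the reconstruction is the percentage-weighted
mean of those optima:  T_July = sum(optimum_s * percent_s) / 100, with
percentages computed over the species that have optima.  Mountain species
whose distribution is not zonal (Microtus nivalis by default) are excluded
from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "SpeciesOptima",
    "FaunalAssemblage",
    "DEFAULT_OPTIMA",
    "DEFAULT_EXCLUDED",
    "reconstruct_tjuly",
    "reconstruct_series",
    "relative_frequencies",
]

logger = logging.getLogger(__name__)

# Modern July temperature optima (deg C) for vole genera/species.
DEFAULT_OPTIMA: dict[str, float] = {
    "Clethrionomys": 15.0,
    "Arvicola": 17.5,
    "Microtus arvalis": 21.0,
    "Microtus agrestis": 19.0,
    "Lasiopodomys gregalis": 10.0,
    "Microtus oeconomus": 12.5,
    "Dicrostonyx": 7.5,
}
DEFAULT_EXCLUDED: frozenset[str] = frozenset({"Microtus nivalis"})

# Synonyms mapping alternative spellings/ranks onto optima-table keys.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Lasiopodomys (S.) gregalis": "Lasiopodomys gregalis",
    "Stenocranius gregalis": "Lasiopodomys gregalis",
    "Microtus gregalis": "Lasiopodomys gregalis",
    "Dicrostonyx torquatus": "Dicrostonyx",
    "Clethrionomys glareolus": "Clethrionomys",
    "Arvicola amphibius": "Arvicola",
    "Arvicola terrestris": "Arvicola",
}


class NoDataError(ValueError):
    """No usable (counted, optimum-bearing, non-excluded) species."""


@dataclass(frozen=True)
class SpeciesOptima:
    """Species -> July temperature optimum table plus the exclusion set."""

    optima: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OPTIMA))
    excluded: frozenset[str] = DEFAULT_EXCLUDED
    synonyms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))

    def resolve(self, name: str) -> str | None:
        """Resolve a taxon name to an optima-table key, or None.

        Exact match first, then the synonym map, then genus-level matching
        against genus-rank table keys (e.g. any *Clethrionomys* species).
        """
        if name in self.optima:
            return name
        if name in self.synonyms and self.synonyms[name] in self.optima:
            return self.synonyms[name]
        genus = name.split()[0]
        if genus in self.optima and " " not in genus:
            return genus
        return None

    def is_excluded(self, name: str) -> bool:
        if name in self.excluded:
            return True
        return self.synonyms.get(name, name) in self.excluded


@dataclass
class FaunalAssemblage:
    """Species counts for one stratigraphic sample."""

    counts: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")


def reconstruct_tjuly(
    assemblage: FaunalAssemblage,
    optima: SpeciesOptima | None = None,
    min_individuals: int = 10,
) -> tuple[float, bool]:
    """Optimum-weighted mean July temperature for one assemblage.

    Returns ``(t_july, low_n_flag)``; the flag marks assemblages with fewer
    than ``min_individuals`` usable specimens.  Species neither in the
    optima table nor excluded are dropped from the denominator and logged.
    """
    optima = optima or SpeciesOptima()
    usable: dict[str, float] = {}
    for sp, n in assemblage.counts.items():
        if n <= 0 or optima.is_excluded(sp):
            continue
        key = optima.resolve(sp)
        if key is None:
            logger.warning("unassigned taxon dropped from vole thermometer: %s", sp)
            continue
        usable[key] = usable.get(key, 0.0) + n
    total = sum(usable.values())
    if total <= 0:
        raise NoDataError(f"no usable species in assemblage {assemblage.label!r}")
    t = sum(optima.optima[k] * (n / total * 100.0) for k, n in usable.items()) / 100.0
    return float(t), total < min_individuals


def reconstruct_series(
    matrix: CountMatrix,
    optima: SpeciesOptima | None = None,
    min_individuals: int = 10,
) -> pd.DataFrame:
    """Downcore T_July for every sample of a faunal count matrix."""
    optima = optima or SpeciesOptima()
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        a = FaunalAssemblage(dict(zip(matrix.taxa, matrix.counts[i])), label=sid)
        try:
            t, low_n = reconstruct_tjuly(a, optima, min_individuals)
        except NoDataError:
            t, low_n = np.nan, True
        rows.append({"sample_id": sid, "t_july": t, "low_n": low_n})
    return pd.DataFrame(rows)


def relative_frequencies(matrix: CountMatrix, group: set[str]) -> pd.DataFrame:
    """Per-sample percentages of each group member over the group total.

    Samples whose group total is zero get an all-missing row, not zeros.
    """
    if not group:
        raise ValueError("group must be non-empty")
    members = [t for t in matrix.taxa if t in group]
    pct = matrix.percentages(members)
    return pd.DataFrame(pct, columns=members, index=matrix.sample_ids)
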