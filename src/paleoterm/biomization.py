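"""Pollen biomization via plant-functional-type affinity scores.

Each pollen taxon belongs to one or more plant functional types (PFTs);
each biome is characterised by a set of PFTs.  A sample's affinity for a
biome is the sum, over that biome's PFTs, of the square roots of the pollen
percentages of the member taxa — counting only taxa above a percentage
threshold (0.5% by default).  The sample is assigned to the biome with the
maximum affinity.  If the winner is temperate forest but the arboreal
pollen sum is below the cutoff (70% by default), wooded steppe is assigned
instead (the open-landscape override).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, FormatError

__all__ = [
    "PftMatrix",
    "BiomeMatrix",
    "AffinityResult",
    "score_affinities",
    "assign_biome",
    "biomize",
    "read_pft_matrix",
    "read_biome_matrix",
]

logger = logging.getLogger(__name__)

TEMPERATE_FOREST = "temperate forest"
WOODED_STEPPE = "wooded steppe"


@dataclass
class PftMatrix:
    """Taxon x PFT 0/1 membership with a per-taxon arboreal flag."""

    taxa: list[str]
    pfts: list[str]
    membership: np.ndarray  # (n_taxa, n_pfts) in {0,1}
    arboreal: np.ndarray  # (n_taxa,) bool

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, int)
        self.arboreal = np.asarray(self.arboreal, bool)
        if self.membership.shape != (len(self.taxa), len(self.pfts)):
            raise FormatError("membership shape must be (n_taxa, n_pfts)")
        if not np.isin(self.membership, (0, 1)).all():
            raise FormatError("membership entries must be 0/1")
        if np.any(self.membership.sum(axis=1) < 1):
            raise FormatError("every taxon must belong to >= 1 PFT")


@dataclass
class BiomeMatrix:
    """Biome x PFT 0/1 membership."""

    biomes: list[str]
    pfts: list[str]
    membership: np.ndarray  # (n_biomes, n_pfts)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, int)
        if self.membership.shape != (len(self.biomes), len(self.pfts)):
            raise FormatError("membership shape must be (n_biomes, n_pfts)")
        if not np.isin(self.membership, (0, 1)).all():
            raise FormatError("membership entries must be 0/1")
        if np.any(self.membership.sum(axis=1) < 1):
            raise FormatError("every biome must have >= 1 PFT")


@dataclass
class AffinityResult:
    scores: dict[str, float]
    assigned: str
    arboreal_percent: float
    override: bool = False
    unassigned_taxa: list[str] = field(default_factory=list)


def read_pft_matrix(path: str | Path) -> PftMatrix:
    """Read a taxa x PFT CSV with an ``arboreal`` column."""
    df = pd.read_csv(path, comment="#")
    if "arboreal" not in df.columns:
        raise FormatError("pft matrix needs an 'arboreal' column")
    taxa = df.iloc[:, 0].astype(str).tolist()
    pft_cols = [c for c in df.columns[1:] if c != "arboreal"]
    return PftMatrix(
        taxa=taxa,
        pfts=pft_cols,
        membership=df[pft_cols].to_numpy(int),
        arboreal=df["arboreal"].to_numpy(bool),
    )


def read_biome_matrix(path: str | Path) -> BiomeMatrix:
    df = pd.read_csv(path, comment="#")
    biomes = df.iloc[:, 0].astype(str).tolist()
    pfts = list(df.columns[1:])
    return BiomeMatrix(biomes=biomes, pfts=pfts, membership=df[pfts].to_numpy(int))


def score_affinities(
    percentages: dict[str, float],
    pft: PftMatrix,
    biomes: BiomeMatrix,
    threshold: float = 0.5,
) -> tuple[dict[str, float], float, list[str]]:
    """Biome affinity scores for one sample of pollen percentages.

    Taxa at or below ``threshold`` percent contribute nothing; above it a
    taxon contributes sqrt(percent) to every PFT it belongs to, and a PFT's
    score accrues to every biome that lists it.  Returns
    ``(scores, arboreal_percent, unassigned_taxa)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    tot = sum(percentages.values())
    if tot <= 0:
        raise ValueError("sample percentages must sum > 0")
    if pft.pfts != biomes.pfts:
        # align biome matrix columns onto the PFT matrix's PFT order
        missing = set(pft.pfts) - set(biomes.pfts)
        if missing:
            raise FormatError(f"biome matrix missing PFTs: {sorted(missing)}")
    taxon_index = {t: i for i, t in enumerate(pft.taxa)}
    pft_scores = np.zeros(len(pft.pfts))
    arboreal_sum = 0.0
    unassigned: list[str] = []
    for taxon, pct in percentages.items():
        i = taxon_index.get(taxon)
        if i is None:
            if pct > 0:
                logger.warning("taxon absent from PFT matrix, ignored: %s", taxon)
                unassigned.append(taxon)
            continue
        if pft.arboreal[i]:
            arboreal_sum += pct
        if pct > threshold:
            pft_scores += pft.membership[i] * np.sqrt(pct)
    biome_cols = [biomes.pfts.index(p) for p in pft.pfts]
    scores = {
        b: float(np.sum(biomes.membership[j, biome_cols] * pft_scores))
        for j, b in enumerate(biomes.biomes)
    }
    return scores, arboreal_sum, unassigned


def assign_biome(
    scores: dict[str, float],
    arboreal_percent: float,
    biomes: BiomeMatrix,
    ap_cutoff: float = 70.0,
) -> tuple[str, bool]:
    """Assign the maximal-affinity biome, with the wooded-steppe override.

    Ties go to the biome defined by the fewest PFTs (the more specific
    biome); a further tie keeps the input biome order.  Returns
    ``(biome, override_flag)``.
    """
    positive = {b: s for b, s in scores.items() if s > 0}
    if not positive:
        return "unassigned", False
    best = max(positive.values())
    tied = [b for b, s in positive.items() if s == best]
    if len(tied) > 1:
        n_pfts = {
            b: int(biomes.membership[biomes.biomes.index(b)].sum()) for b in tied
        }
        fewest = min(n_pfts.values())
        tied = [b for b in biomes.biomes if b in tied and n_pfts[b] == fewest]
    winner = tied[0]
    if winner == TEMPERATE_FOREST and arboreal_percent < ap_cutoff:
        return WOODED_STEPPE, True
    return winner, False


def biomize(
    matrix: CountMatrix,
    pft: PftMatrix,
    biomes: BiomeMatrix,
    threshold: float = 0.5,
    ap_cutoff: float = 70.0,
) -> list[AffinityResult]:
    """Score and assign every sample of a downcore pollen matrix."""
    pct = matrix.counts if matrix.is_percent else matrix.percentages()
    results = []
    for i in range(matrix.n_samples):
        sample = dict(zip(matrix.taxa, pct[i]))
        scores, ap, unassigned = score_affinities(sample, pft, biomes, threshold)
        label, override = assign_biome(scores, ap, biomes, ap_cutoff)
        results.append(
            AffinityResult(
                scores=scores,
                assigned=label,
                arboreal_percent=ap,
                override=override,
                unassigned_taxa=unassigned,
            )
        )
    return results
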