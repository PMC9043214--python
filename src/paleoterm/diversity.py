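"""Palynological richness (rarefaction) and assemblage evenness.

Richness is Hurlbert's rarefaction E(T): the expected number of taxa in a
random draw of ``base_n`` grains without replacement,

    E(T) = sum_k [ 1 - C(N - N_k, n) / C(N, n) ],

evaluated with log-gamma arithmetic for stability.  Evenness is Pielou's
J' = H'/ln(S) by default, with the Hill-number ratio N2/N1 as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CountMatrix

__all__ = ["rarefied_richness", "evenness", "diversity_table"]


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts: np.ndarray, base_n: int) -> float:
    """Expected taxon count E(T) at draw size ``base_n`` (Hurlbert)."""
    counts = np.asarray(counts)
    if not np.all(counts == np.floor(counts)):
        raise ValueError("rarefaction needs integer counts, not percentages")
    counts = counts[counts > 0].astype(np.int64)
    if counts.size == 0:
        raise ValueError("empty assemblage")
    total = int(counts.sum())
    if not 1 <= base_n <= total:
        raise ValueError(f"base_n must be in [1, {total}], got {base_n}")
    # P(taxon k absent from the draw) = C(N - N_k, n)/C(N, n)
    rem = total - counts
    with np.errstate(invalid="ignore"):
        log_p_absent = _log_choose(rem, base_n) - _log_choose(total, base_n)
    p_absent = np.where(rem >= base_n, np.exp(log_p_absent), 0.0)
    return float(np.sum(1.0 - p_absent))


def evenness(counts: np.ndarray, index: str = "pielou") -> float:
    """Abundance-distribution evenness of one assemblage.

    ``pielou``: Shannon H' divided by ln(S); undefined (NaN) for a single
    taxon.  ``hill_ratio``: Hill N2/N1 = (1/sum p^2) / exp(H').
    """
    counts = np.asarray(counts, float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty assemblage")
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    if index == "pielou":
        if counts.size == 1:
            return float("nan")
        return float(h / np.log(counts.size))
    if index == "hill_ratio":
        n1 = np.exp(h)
        n2 = 1.0 / np.sum(p**2)
        return float(n2 / n1)
    raise ValueError(f"unknown evenness index: {index!r}")


def diversity_table(
    matrix: CountMatrix,
    base_n: int | None = None,
    index: str = "pielou",
) -> pd.DataFrame:
    """Per-sample E(T) and evenness for a downcore count matrix.

    ``base_n=None`` uses the minimum sample total across samples with any
    counts, so values are comparable downcore.
    """
    if matrix.is_percent:
        raise ValueError("rarefaction needs counts; this table holds percentages")
    totals = matrix.row_totals()
    if base_n is None:
        pos = totals[totals > 0]
        if pos.size == 0:
            raise ValueError("no non-empty samples")
        base_n = int(pos.min())
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        c = matrix.counts[i]
        if totals[i] <= 0 or totals[i] < base_n:
            rows.append({"sample_id": sid, "e_t": np.nan, "evenness": np.nan,
                         "total": int(totals[i])})
            continue
        rows.append(
            {
                "sample_id": sid,
                "e_t": rarefied_richness(c, base_n),
                "evenness": evenness(c, index),
                "total": int(totals[i]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["base_n"] = base_n
    out.attrs["evenness_index"] = index
    return out
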