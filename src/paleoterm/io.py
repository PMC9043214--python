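"""Readers and writers for the tabular formats the pipeline touches.

All tables are CSV (comma separated, ``.`` decimal, UTF-8, ``#`` comment
lines).  Ages are years cal BP (before AD 1950, larger = older); depths are
cm, positive downward.  Every reader validates its invariants on load and is
the exact inverse of the matching writer on valid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CalibrationCurve",
    "CountMatrix",
    "DatedRecordTable",
    "read_calcurve",
    "write_calcurve",
    "read_counts",
    "write_counts",
    "read_dated_records",
    "write_dated_records",
]


class FormatError(ValueError):
    """A file violates the dialect or a domain invariant."""


# ---------------------------------------------------------------------------
# Calibration curve


@dataclass(frozen=True)
class CalibrationCurve:
    """A calendar-age -> radiocarbon-age mapping with 1-sigma uncertainty.

    Parameters
    ----------
    cal_age : array
        Calendar ages, years cal BP, strictly increasing.
    c14_age : array
        Conventional radiocarbon age at each grid point, 14C yr BP.
    sigma : array
        One-sigma uncertainty of ``c14_age`` at each grid point, 14C yr.
    """

    cal_age: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_age", np.asarray(self.cal_age, float))
        object.__setattr__(self, "c14_age", np.asarray(self.c14_age, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        n = self.cal_age.size
        if n < 2 or self.c14_age.size != n or self.sigma.size != n:
            raise FormatError("curve arrays must have equal length >= 2")
        if np.any(np.diff(self.cal_age) <= 0):
            raise FormatError("cal_age must be strictly increasing")
        if np.any(self.sigma < 0):
            raise FormatError("curve sigma must be >= 0")

    def c14_at(self, cal_age: np.ndarray) -> np.ndarray:
        """Linearly interpolated 14C age at arbitrary calendar ages."""
        return np.interp(cal_age, self.cal_age, self.c14_age)

    def sigma_at(self, cal_age: np.ndarray) -> np.ndarray:
        """Linearly interpolated curve 1-sigma at arbitrary calendar ages."""
        return np.interp(cal_age, self.cal_age, self.sigma)


def read_calcurve(path: str | Path, dialect: str = "simple") -> CalibrationCurve:
    """Read a calibration curve file.

    ``dialect='simple'`` is a 3-column CSV (cal BP, 14C age, sigma);
    ``dialect='intcal'`` is the IntCal distribution layout: ``#`` header
    lines, 5+ columns, of which only the first three are used.  Rows are
    re-sorted ascending in cal age; duplicated calendar ages are collapsed
    only when their 14C ages agree.
    """
    if dialect not in ("simple", "intcal"):
        raise ValueError(f"unknown curve dialect: {dialect!r}")
    df = pd.read_csv(path, comment="#", header=None)
    if df.shape[1] < 3:
        raise FormatError("curve file needs at least 3 columns")
    # some simple files carry a header row; drop non-numeric leading rows
    df = df.apply(pd.to_numeric, errors="coerce").dropna(subset=[0, 1, 2])
    arr = df.iloc[:, :3].to_numpy(float)
    if arr.shape[0] < 2:
        raise FormatError("curve needs >= 2 numeric rows")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    cal, idx = np.unique(arr[:, 0], return_index=True)
    if cal.size != arr.shape[0]:
        # duplicated cal ages are only tolerable if the duplicates agree
        for v in cal:
            rows = arr[arr[:, 0] == v]
            if not np.allclose(rows, rows[0]):
                raise FormatError(f"conflicting duplicate rows at cal age {v}")
        arr = arr[idx]
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def write_calcurve(curve: CalibrationCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {"cal_age": curve.cal_age, "c14_age": curve.c14_age, "sigma": curve.sigma}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# calibration curve: cal BP, 14C age BP, 1-sigma\n")
        df.to_csv(fh, header=False, index=False)


# ---------------------------------------------------------------------------
# Count matrices

_META_COLS = ("depth", "age")
PERCENT_TOL = 1.5  # row sums within 100 +/- this in every row -> percent table


@dataclass
class CountMatrix:
    """Samples x taxa abundance table with optional depth/age metadata.

    ``counts`` holds raw counts or percentages; ``is_percent`` flags which.
    Percentage tables are auto-detected on read: every row sum within
    100 +/- 1.5 flags the table as percent.
    """

    sample_ids: list[str]
    taxa: list[str]
    counts: np.ndarray
    depths: np.ndarray | None = None
    ages: np.ndarray | None = None
    is_percent: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (len(self.sample_ids), len(self.taxa)):
            raise FormatError("counts shape must be (n_samples, n_taxa)")
        if np.any(self.counts < 0):
            raise FormatError("negative count")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicated taxon column")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def percentages(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Row percentages over ``taxa`` (default: all).

        Rows whose group total is zero come back as all-NaN, not zeros.
        """
        if taxa is None:
            sub = self.counts
        else:
            idx = [self.taxa.index(t) for t in taxa]
            sub = self.counts[:, idx]
        tot = sub.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(tot > 0, sub / tot * 100.0, np.nan)
        return pct

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.taxa)
        df.insert(0, "sample_id", self.sample_ids)
        pos = 1
        if self.depths is not None:
            df.insert(pos, "depth", self.depths)
            pos += 1
        if self.ages is not None:
            df.insert(pos, "age", self.ages)
        return df


def read_counts(path: str | Path) -> CountMatrix:
    """Read a samples x taxa CSV: first column sample id, optional
    ``depth``/``age`` columns, remaining columns taxa."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError("count table needs a sample-id column plus taxa")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    rest = df.iloc[:, 1:]
    depths = ages = None
    taxa_cols = []
    for col in rest.columns:
        if col.lower() == "depth":
            depths = rest[col].to_numpy(float)
        elif col.lower() == "age":
            ages = rest[col].to_numpy(float)
        else:
            taxa_cols.append(col)
    if len(set(taxa_cols)) != len(taxa_cols):
        raise FormatError("duplicated taxon column")
    counts = rest[taxa_cols].to_numpy(float)
    if np.any(np.isnan(counts)):
        raise FormatError("non-numeric or missing count value")
    if np.any(counts < 0):
        raise FormatError("negative count")
    totals = counts.sum(axis=1)
    is_percent = bool(totals.size and np.all(np.abs(totals - 100.0) <= PERCENT_TOL))
    return CountMatrix(
        sample_ids=sample_ids,
        taxa=[str(t) for t in taxa_cols],
        counts=counts,
        depths=depths,
        ages=ages,
        is_percent=is_percent,
    )


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dated records

_REQUIRED_RECORD_COLS = ("taxon", "age", "sigma", "age_type")


@dataclass
class DatedRecordTable:
    """Dated records (bones, charcoal...) for extinction inference.

    One row per dated specimen: taxon, lab code, age (14C or calibrated,
    years BP), 1-sigma, stratigraphic position and an inclusion flag used
    to reproduce published exclusions (burnt bones, problematic sites).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        for col in _REQUIRED_RECORD_COLS:
            if col not in df.columns:
                raise FormatError(f"missing required column: {col}")
        if "lab_code" not in df.columns:
            df = df.assign(lab_code="")
        if "depth" not in df.columns:
            df = df.assign(depth=np.nan)
        if "include_flag" not in df.columns:
            df = df.assign(include_flag=True)
        df = df.copy()
        df["age"] = pd.to_numeric(df["age"])
        df["sigma"] = pd.to_numeric(df["sigma"])
        df["include_flag"] = df["include_flag"].astype(bool)
        if (df["sigma"] <= 0).any():
            raise FormatError("sigma must be > 0")
        bad = ~df["age_type"].isin(["c14", "calibrated"])
        if bad.any():
            raise FormatError(f"age_type must be c14|calibrated, got {df.loc[bad, 'age_type'].unique()}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def filter(self, taxon: str | None = None, included_only: bool = True) -> "DatedRecordTable":
        df = self.frame
        if taxon is not None:
            df = df[df["taxon"] == taxon]
        if included_only:
            df = df[df["include_flag"]]
        return DatedRecordTable(df.reset_index(drop=True))


def read_dated_records(path: str | Path) -> DatedRecordTable:
    df = pd.read_csv(path, comment="#")
    return DatedRecordTable(df)


def write_dated_records(t: DatedRecordTable, path: str | Path) -> None:
    cols = ["taxon", "lab_code", "age", "sigma", "age_type", "depth", "include_flag"]
    t.frame[cols].to_csv(path, index=False)
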