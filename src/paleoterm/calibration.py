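"""Radiocarbon calibration: posterior calendar-age densities, HPD intervals
and point estimates.

A radiocarbon determination ``c14_age +/- sigma`` is converted into a
normalized posterior over calendar ages by evaluating, on a regular calendar
grid, the likelihood of the measured 14C age under the calibration curve:

    p(t) ∝ N(c14_age; mu(t), sqrt(sigma^2 + s(t)^2))

where ``mu(t)`` and ``s(t)`` are the curve's 14C age and 1-sigma linearly
interpolated at calendar age ``t``.  The prior over calendar age is uniform
on the grid, so the normalized likelihood is the posterior.  No reservoir or
offset corrections are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CalibrationCurve

__all__ = [
    "RadiocarbonDetermination",
    "CalendarAgeDensity",
    "CalibrationRangeError",
    "calibrate",
    "hpd_interval",
    "point_estimate",
]

_TRUNCATE_REL = 1e-12  # drop grid mass below this fraction of the peak
_NORM_TOL = 1e-9


class CalibrationRangeError(ValueError):
    """Determination lies entirely outside the calibration curve support."""


@dataclass(frozen=True)
class RadiocarbonDetermination:
    """A conventional radiocarbon measurement, 14C yr BP with 1-sigma error."""

    c14_age: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class CalendarAgeDensity:
    """Probability mass per cell on a strictly increasing calendar-age grid."""

    cal_age: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_age", np.asarray(self.cal_age, float))
        object.__setattr__(self, "mass", np.asarray(self.mass, float))
        if self.cal_age.size != self.mass.size or self.cal_age.size == 0:
            raise ValueError("grid and mass must have equal nonzero length")
        if self.cal_age.size > 1 and np.any(np.diff(self.cal_age) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("negative probability mass")
        if abs(self.mass.sum() - 1.0) > _NORM_TOL:
            raise ValueError("mass must sum to 1 within 1e-9")


def calibrate(
    det: RadiocarbonDetermination,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
) -> CalendarAgeDensity:
    """Calibrate one determination against a curve on a regular grid.

    The grid spans the curve's calendar range at ``grid_step`` yr spacing;
    cells with mass below 1e-12 of the peak are truncated away and the rest
    renormalized to sum to one.

    Raises
    ------
    CalibrationRangeError
        If the determination lies more than 10 combined sigma outside the
        curve's 14C range everywhere.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    grid = np.arange(curve.cal_age[0], curve.cal_age[-1] + grid_step / 2, grid_step)
    mu = curve.c14_at(grid)
    sd = np.sqrt(det.sigma**2 + curve.sigma_at(grid) ** 2)
    z = (det.c14_age - mu) / sd
    if np.min(np.abs(z)) > 10.0:
        raise CalibrationRangeError(
            f"determination {det.c14_age}+/-{det.sigma} outside curve support"
        )
    logp = stats.norm.logpdf(z) - np.log(sd)
    logp -= logp.max()
    dens = np.exp(logp)
    keep = dens >= _TRUNCATE_REL
    # keep a contiguous block so the grid stays regular
    idx = np.flatnonzero(keep)
    grid, dens = grid[idx[0] : idx[-1] + 1], dens[idx[0] : idx[-1] + 1]
    mass = dens / dens.sum()
    return CalendarAgeDensity(grid, mass)


def hpd_interval(
    d: CalendarAgeDensity, level: float = 0.95
) -> tuple[list[tuple[float, float]], float]:
    """Highest-posterior-density region at the given probability level.

    Returns the smallest set of grid cells (by cell count, filling in
    decreasing-mass order) whose total mass reaches ``level``, merged into
    maximal contiguous ``(young, old)`` intervals, plus the mass actually
    contained.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    order = np.argsort(d.mass, kind="stable")[::-1]
    cum = np.cumsum(d.mass[order])
    ncells = int(np.searchsorted(cum, level) + 1)
    chosen = np.sort(order[:ncells])
    total = float(d.mass[chosen].sum())
    intervals: list[tuple[float, float]] = []
    start = prev = chosen[0]
    for i in chosen[1:]:
        if i == prev + 1:
            prev = i
            continue
        intervals.append((float(d.cal_age[start]), float(d.cal_age[prev])))
        start = prev = i
    intervals.append((float(d.cal_age[start]), float(d.cal_age[prev])))
    return intervals, total


def point_estimate(d: CalendarAgeDensity, kind: str = "median") -> float:
    """Point summary of a calendar-age density.

    median
        Smallest grid age whose cumulative mass reaches 0.5.
    mode
        Argmax of the mass; ties broken toward the older age.
    mean
        Mass-weighted average age.
    """
    if kind == "median":
        return float(d.cal_age[np.searchsorted(np.cumsum(d.mass), 0.5)])
    if kind == "mode":
        peak = d.mass.max()
        return float(d.cal_age[np.flatnonzero(d.mass == peak)[-1]])
    if kind == "mean":
        return float(np.sum(d.cal_age * d.mass))
    raise ValueError(f"unknown point estimate kind: {kind!r}")
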