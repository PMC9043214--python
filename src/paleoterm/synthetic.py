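"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed): an independent RNG
stream is derived from the master seed and the generator's name, so adding
a generator never perturbs existing fixtures.  The generated structures are
the study conditions the estimators are validated under — sighting series
with uniform recovery and Gaussian dating error, a monotone wiggly
calibration curve, Gaussian (unimodal) species-temperature responses with
multinomial counting noise, and downcore sequences driven by a known
temperature trajectory.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from .extinction import SightingSeries
from .io import CalibrationCurve, CountMatrix
from .transfer import TrainingSet

__all__ = [
    "gen_calcurve",
    "gen_sightings",
    "gen_training_set",
    "gen_fossil_sequence",
    "write_truth",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialise a ground-truth record next to its generated dataset."""

    def _convert(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: _convert(v) for k, v in truth.items()}, fh, indent=1)


def gen_calcurve(
    span: float = 10_000.0,
    wiggle_amplitude: float = 20.0,
    seed: int = 0,
    start: float = 0.0,
    step: float = 5.0,
    curve_sigma: float = 10.0,
    plateau: bool = False,
) -> tuple[CalibrationCurve, dict]:
    """Monotone baseline (14C age = cal age on average) plus smooth seeded
    wiggles; the optional plateau inserts a local 14C-age inversion so a
    determination there calibrates to a multimodal density.

    Raises if the wiggles are large enough to destroy the monotonicity of
    the 14C ages (outside plateau mode), which would silently make every
    calibration multimodal.
    """
    if span < 1000:
        raise ValueError("span must be >= 1000 yr")
    rng = _rng(seed, "calcurve")
    cal = np.arange(start, start + span + step / 2, step)
    c14 = cal.astype(float).copy()
    if wiggle_amplitude > 0:
        for _ in range(4):
            period = rng.uniform(span / 20, span / 4)
            phase = rng.uniform(0, 2 * np.pi)
            c14 += (wiggle_amplitude / 4) * np.sin(2 * np.pi * cal / period + phase)
    if plateau:
        center = start + span / 2
        width = max(span / 40, 4 * step)
        c14 -= 3.0 * width * np.exp(-(((cal - center) / width) ** 2))
    elif np.any(np.diff(c14) <= 0):
        raise ValueError("wiggle amplitude breaks curve monotonicity")
    sigma = np.full_like(cal, float(curve_sigma))
    truth = {
        "generator": "calcurve",
        "seed": seed,
        "span": span,
        "wiggle_amplitude": wiggle_amplitude,
        "plateau": plateau,
        "plateau_center": start + span / 2 if plateau else None,
    }
    return CalibrationCurve(cal, c14, sigma), truth


def gen_sightings(
    true_extinction: float = 12_000.0,
    window: float = 5_000.0,
    n: int = 15,
    dating_sd: float = 100.0,
    seed: int = 0,
    taxon: str = "synthetic taxon",
) -> tuple[SightingSeries, dict]:
    """Dated records with uniform recovery over the occupied interval.

    True ages are Uniform(true_extinction, true_extinction + window); the
    observed ages add Gaussian dating error, so the youngest observation can
    fall below the true extinction time.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed, "sightings")
    true_ages = rng.uniform(true_extinction, true_extinction + window, size=n)
    observed = true_ages + rng.standard_normal(n) * dating_sd
    series = SightingSeries(
        ages=observed, sds=np.full(n, float(dating_sd)), taxon=taxon
    )
    truth = {
        "generator": "sightings",
        "seed": seed,
        "true_extinction": true_extinction,
        "window": window,
        "n": n,
        "dating_sd": dating_sd,
        "true_ages": true_ages,
    }
    return series, truth


def gen_training_set(
    n_taxa: int = 40,
    n_samples: int = 150,
    optima_range: tuple[float, float] = (5.0, 25.0),
    tolerance: float = 2.0,
    grains_per_sample: int = 300,
    seed: int = 0,
) -> tuple[TrainingSet, dict]:
    """Modern calibration set under Gaussian species-temperature responses.

    Sample climates are uniform on ``optima_range``; a taxon's expected
    share is proportional to a Gaussian response around its optimum with a
    common tolerance; counts are multinomial draws of
    ``grains_per_sample`` grains.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _rng(seed, "training")
    lo, hi = optima_range
    optima = np.sort(rng.uniform(lo, hi, size=n_taxa))
    climates = rng.uniform(lo, hi, size=n_samples)
    counts = _response_counts(climates, optima, tolerance, grains_per_sample, rng)
    taxa = [f"taxon_{i:02d}" for i in range(n_taxa)]
    matrix = CountMatrix(
        sample_ids=[f"mod_{i:03d}" for i in range(n_samples)],
        taxa=taxa,
        counts=counts,
    )
    truth = {
        "generator": "training",
        "seed": seed,
        "taxa": taxa,
        "optima": optima,
        "tolerance": tolerance,
        "climates": climates,
        "optima_range": list(optima_range),
        "grains_per_sample": grains_per_sample,
    }
    return TrainingSet(counts=matrix, climate=climates), truth


def _response_counts(
    temps: np.ndarray,
    optima: np.ndarray,
    tolerance: float,
    grains: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if np.isinf(tolerance):
        expected = np.ones((temps.size, optima.size))
    else:
        expected = np.exp(
            -((temps[:, None] - optima[None, :]) ** 2) / (2 * tolerance**2)
        )
    expected += 1e-12  # multinomial needs a valid simplex even off-gradient
    probs = expected / expected.sum(axis=1, keepdims=True)
    return np.array([rng.multinomial(grains, p) for p in probs], dtype=float)


def gen_fossil_sequence(
    trajectory: np.ndarray,
    training_truth: dict,
    grains: int = 300,
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """Downcore pollen counts generated from the training set's response
    model at the trajectory's temperatures (oldest sample last)."""
    trajectory = np.asarray(trajectory, float)
    lo, hi = training_truth["optima_range"]
    if np.any((trajectory < lo) | (trajectory > hi)):
        import warnings

        warnings.warn("trajectory leaves the training range: extrapolation mode")
    rng = _rng(seed, "fossil")
    optima = np.asarray(training_truth["optima"], float)
    counts = _response_counts(
        trajectory, optima, float(training_truth["tolerance"]), grains, rng
    )
    matrix = CountMatrix(
        sample_ids=[f"fos_{i:03d}" for i in range(trajectory.size)],
        taxa=list(training_truth["taxa"]),
        counts=counts,
    )
    truth = {
        "generator": "fossil",
        "seed": seed,
        "trajectory": trajectory,
        "grains": grains,
        "training_seed": training_truth.get("seed"),
    }
    return matrix, truth
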