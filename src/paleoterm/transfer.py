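"""Pollen-climate transfer functions: WA-PLS and the modern analogue technique.

Both methods are exposed as scikit-learn style regressors so they compose
with sklearn model selection, plus thin module-level functions mirroring the
pipeline vocabulary (fit / predict / cross-validate / bootstrap / MAT
threshold / reconstruction significance).

WA-PLS (weighted-averaging partial least squares) calibrates taxon
percentages against a single climate variable.  Component 1 is classical
two-way weighted averaging with inverse deshrinking; higher components are
extracted from the weighted regression residuals, orthogonalised against
earlier components, so that systematic structure missed by plain WA is
recovered.  Because every step is affine in the sample's taxon proportions,
the fitted model collapses to one coefficient vector per component count:

    x_hat = b0_A + sum_k q_k * beta_Ak,   q = row proportions (after the
                                          optional square-root transform)

The modern analogue technique (MAT) predicts by inverse-distance-weighted
averaging of the climate of the k compositionally closest modern samples
under the chord distance (Euclidean distance between square-rooted
proportion vectors); analogues beyond a dissimilarity threshold are
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix

__all__ = [
    "TrainingSet",
    "CvStatistics",
    "WAPLS",
    "MATRegressor",
    "DegenerateFitError",
    "chord_distance_matrix",
    "wapls_fit",
    "wapls_predict",
    "loo_crossvalidate",
    "select_component",
    "bootstrap_errors",
    "mat_reconstruct",
    "mat_threshold",
    "reconstruction_significance",
]

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """The climate gradient is exhausted (e.g. constant) for the requested
    number of components."""


@dataclass
class TrainingSet:
    """Modern calibration data: percentage matrix plus one climate value per
    sample (T_JJA in the reference use)."""

    counts: CountMatrix
    climate: np.ndarray

    def __post_init__(self) -> None:
        self.climate = np.asarray(self.climate, float)
        if self.climate.size != self.counts.n_samples:
            raise ValueError("one climate value per sample required")
        if not np.all(np.isfinite(self.climate)):
            raise ValueError("climate values must be finite")


@dataclass
class CvStatistics:
    """Leave-one-out performance per WA-PLS component."""

    r2: np.ndarray
    rmsep: np.ndarray
    max_bias: np.ndarray
    predictions: np.ndarray = field(repr=False)  # (n_samples, n_components)
    observed: np.ndarray = field(repr=False)
    selected: int | None = None
    p_values: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.r2.size


# ---------------------------------------------------------------------------
# shared helpers


def _to_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, CountMatrix):
        return np.asarray(X.counts, float), list(X.taxa)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    return np.asarray(X, float), None


def _proportions(Y: np.ndarray) -> np.ndarray:
    tot = Y.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, Y / tot, np.nan)


def chord_distance_matrix(P: np.ndarray, Q: np.ndarray, squared: bool = False) -> np.ndarray:
    """Chord distances between rows of two proportion matrices.

    Chord distance = Euclidean distance between square-rooted proportion
    vectors; ``squared=True`` gives the squared-chord variant.
    """
    a, b = np.sqrt(P), np.sqrt(Q)
    d2 = np.maximum(
        (a**2).sum(1)[:, None] + (b**2).sum(1)[None, :] - 2 * a @ b.T, 0.0
    )
    return d2 if squared else np.sqrt(d2)


def _match_taxa(
    fossil_taxa: list[str] | None, model_taxa: list[str], n_cols: int
) -> tuple[np.ndarray, np.ndarray]:
    """Column indices mapping fossil columns onto the model's taxon order.

    Returns (fossil_idx, model_idx): paired columns.  Without names, columns
    are assumed already aligned.
    """
    if fossil_taxa is None:
        if n_cols != len(model_taxa):
            raise ValueError(
                "unnamed fossil matrix must match the training taxon count"
            )
        idx = np.arange(n_cols)
        return idx, idx
    lookup = {t: j for j, t in enumerate(model_taxa)}
    pairs = [(i, lookup[t]) for i, t in enumerate(fossil_taxa) if t in lookup]
    dropped = [t for t in fossil_taxa if t not in lookup]
    if dropped:
        logger.warning("fossil taxa absent from training set dropped: %s", dropped)
    if not pairs:
        raise ValueError("fossil data share no taxa with the training set")
    fi, mi = zip(*pairs)
    return np.asarray(fi), np.asarray(mi)


# ---------------------------------------------------------------------------
# WA-PLS


class WAPLS(RegressorMixin, BaseEstimator):
    """Weighted-averaging partial least squares calibration.

    Parameters
    ----------
    n_components : int
        Number of WA-PLS components to extract (the fitted maximum).
    sqrt_transform : bool
        Square-root transform the percentages before fitting, the standard
        noise-reduction choice for pollen data.

    Attributes
    ----------
    taxa_ : list of str or None
        Training taxon names (from DataFrame/CountMatrix input).
    coefficients_ : ndarray, (n_components, n_taxa)
        Per-taxon prediction coefficients for each component count.
    intercepts_ : ndarray, (n_components,)
    x_mean_ : float
        Abundance-weighted mean of the training climate.
    """

    def __init__(self, n_components: int = 5, sqrt_transform: bool = True):
        self.n_components = n_components
        self.sqrt_transform = sqrt_transform

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        Y, taxa = _to_matrix(X)
        x = np.asarray(y, float)
        if Y.ndim != 2 or x.ndim != 1 or Y.shape[0] != x.size:
            raise ValueError("X must be (n_samples, n_taxa), y (n_samples,)")
        if np.any(Y < 0):
            raise ValueError("negative abundance")
        if Y.shape[0] < 2:
            raise ValueError("need >= 2 training samples")
        keep = Y.sum(axis=0) > 0
        if not keep.all():
            dropped = (
                [t for t, k in zip(taxa, keep) if not k] if taxa else
                list(np.flatnonzero(~keep))
            )
            logger.warning("taxa with zero total abundance dropped: %s", dropped)
        Y = Y[:, keep]
        taxa = [t for t, k in zip(taxa, keep) if k] if taxa else None
        if np.any(Y.sum(axis=1) <= 0):
            raise ValueError("training sample with zero total abundance")
        A = int(self.n_components)
        if not 1 <= A <= min(Y.shape[1], Y.shape[0] - 1):
            raise ValueError("n_components must be in [1, min(taxa, samples-1)]")
        # percentages over the included taxa, then optional sqrt
        Y = _proportions(Y) * 100.0
        if self.sqrt_transform:
            Y = np.sqrt(Y)
        R = Y.sum(axis=1)  # sample weights
        K = Y.sum(axis=0)  # taxon weights
        W = R / R.sum()
        xbar = float(np.sum(W * x))
        if np.ptp(x) == 0:
            if A > 1:
                raise DegenerateFitError(
                    "constant climate vector supports only 1 component"
                )
            self._finalize(taxa, np.zeros((1, Y.shape[1])), np.array([xbar]), xbar)
            return self
        Q = Y / Y.sum(axis=1, keepdims=True)  # row proportions of transformed data
        resid = x - xbar
        comps: list[np.ndarray] = []  # standardized site scores p_a
        u_list: list[np.ndarray] = []
        nu_list: list[np.ndarray] = []  # orthogonalisation coefs vs previous axes
        mu_list: list[float] = []
        sd_list: list[float] = []
        betas = np.empty(A)
        coef_rows = np.empty((A, Y.shape[1]))
        intercepts = np.empty(A)
        c_list: list[np.ndarray] = []  # affine rep: p_a(q) = q @ c_a + d_a
        d_list: list[float] = []
        for a in range(A):
            u = (Y * resid[:, None]).sum(axis=0) / K  # species scores
            s = Q @ u  # site scores
            nu = np.empty(a)
            for b in range(a):
                nu[b] = float(np.sum(W * s * comps[b]))
                s = s - nu[b] * comps[b]
            mu = float(np.sum(W * s))
            var = float(np.sum(W * (s - mu) ** 2))
            if var < 1e-14:
                raise DegenerateFitError(
                    f"gradient exhausted at component {a + 1}"
                )
            sd = np.sqrt(var)
            p = (s - mu) / sd
            comps.append(p)
            u_list.append(u)
            nu_list.append(nu)
            mu_list.append(mu)
            sd_list.append(sd)
            # weighted regression of x on orthonormal components
            betas[a] = float(np.sum(W * x * p))
            fitted = xbar + sum(betas[b] * comps[b] for b in range(a + 1))
            resid = x - fitted
            # affine representation for prediction
            c = u.copy()
            d = 0.0
            for b in range(a):
                c = c - nu[b] * c_list[b]
                d = d - nu[b] * d_list[b]
            c = c / sd
            d = (d - mu) / sd
            c_list.append(c)
            d_list.append(d)
            coef_rows[a] = sum(betas[b] * c_list[b] for b in range(a + 1))
            intercepts[a] = xbar + sum(betas[b] * d_list[b] for b in range(a + 1))
        self._finalize(taxa, coef_rows, intercepts, xbar)
        return self

    def _finalize(self, taxa, coefs, intercepts, xbar) -> None:
        self.taxa_ = taxa
        self.coefficients_ = coefs
        self.intercepts_ = intercepts
        self.x_mean_ = xbar
        self.n_components_ = coefs.shape[0]
        self.n_features_in_ = coefs.shape[1]

    # -- prediction ---------------------------------------------------------

    def predict(self, X, component: int | None = None) -> np.ndarray:
        """Predict climate for fossil (or modern) samples.

        ``component`` selects the component count (default: the fitted
        maximum).  Rows with zero usable abundance yield NaN.
        """
        check_is_fitted(self, "coefficients_")
        a = self.n_components_ if component is None else int(component)
        if not 1 <= a <= self.n_components_:
            raise ValueError(f"component must be in [1, {self.n_components_}]")
        F, fossil_taxa = _to_matrix(X)
        if F.ndim == 1:
            F = F[None, :]
        fi, mi = _match_taxa(
            fossil_taxa, self.taxa_ or list(range(self.n_features_in_)), F.shape[1]
        )
        sub = np.zeros((F.shape[0], self.n_features_in_))
        sub[:, mi] = F[:, fi]
        if np.any(sub < 0):
            raise ValueError("negative abundance")
        pct = _proportions(sub) * 100.0  # NaN rows propagate
        if self.sqrt_transform:
            pct = np.sqrt(pct)
        q = pct / pct.sum(axis=1, keepdims=True)
        return self.intercepts_[a - 1] + q @ self.coefficients_[a - 1]


def wapls_fit(t: TrainingSet, n_components: int = 5, sqrt_transform: bool = True) -> WAPLS:
    return WAPLS(n_components=n_components, sqrt_transform=sqrt_transform).fit(
        t.counts, t.climate
    )


def wapls_predict(
    model: WAPLS, fossil: CountMatrix, component: int | None = None
) -> pd.DataFrame:
    est = model.predict(fossil, component=component)
    return pd.DataFrame(
        {
            "sample_id": fossil.sample_ids,
            "estimate": est,
            "no_overlap": ~np.isfinite(est),
        }
    )


# ---------------------------------------------------------------------------
# validation suite


def _max_bias(obs: np.ndarray, pred: np.ndarray, n_bins: int = 10) -> float:
    """Largest |mean residual| over equal-width intervals of the gradient."""
    resid = pred - obs
    edges = np.linspace(obs.min(), obs.max(), n_bins + 1)
    worst = 0.0
    for j in range(n_bins):
        hi_ok = obs <= edges[j + 1] if j == n_bins - 1 else obs < edges[j + 1]
        m = (obs >= edges[j]) & hi_ok
        if m.any():
            worst = max(worst, abs(float(resid[m].mean())))
    return worst


def loo_crossvalidate(
    t: TrainingSet, max_components: int = 5, sqrt_transform: bool = True
) -> CvStatistics:
    """Leave-one-out cross-validation of WA-PLS, per component count."""
    Y, taxa = _to_matrix(t.counts)
    x = t.climate
    n = x.size
    A = int(max_components)
    preds = np.full((n, A), np.nan)
    cols = [str(i) for i in range(Y.shape[1])] if taxa is None else taxa
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        sub = pd.DataFrame(Y[mask], columns=cols)
        a_i = min(A, int(mask.sum()) - 1)
        m = WAPLS(n_components=a_i, sqrt_transform=sqrt_transform).fit(sub, x[mask])
        row = pd.DataFrame(Y[i : i + 1], columns=cols)
        for a in range(1, a_i + 1):
            preds[i, a - 1] = m.predict(row, component=a)[0]
    r2 = np.empty(A)
    rmsep = np.empty(A)
    mbias = np.empty(A)
    for a in range(A):
        p = preds[:, a]
        ok = np.isfinite(p)
        r = np.corrcoef(x[ok], p[ok])[0, 1]
        r2[a] = r**2
        rmsep[a] = float(np.sqrt(np.mean((p[ok] - x[ok]) ** 2)))
        mbias[a] = _max_bias(x[ok], p[ok])
    return CvStatistics(r2=r2, rmsep=rmsep, max_bias=mbias, predictions=preds, observed=x)


def select_component(
    cv: CvStatistics, n_randomizations: int = 999, seed: int | None = None
) -> int:
    """Pick the WA-PLS component count by a randomization paired test.

    Component c+1 is accepted over c only if it lowers RMSEP and the mean
    per-sample squared-error reduction is significant (p < 0.05) under
    sign-flip randomization; the walk stops at the first rejection.
    The p-values, (r+1)/(n+1), are stored on ``cv``.
    """
    if cv.n_components < 2:
        cv.selected = 1
        return 1
    rng = np.random.default_rng(seed)
    errs = (cv.predictions - cv.observed[:, None]) ** 2
    p_values = np.full(cv.n_components, np.nan)
    selected = 1
    for c in range(1, cv.n_components):
        if not np.isfinite(cv.rmsep[c]) or cv.rmsep[c] >= cv.rmsep[c - 1]:
            break
        d = errs[:, c - 1] - errs[:, c]  # positive = improvement
        d = d[np.isfinite(d)]
        obs = d.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_randomizations, d.size))
        null = (signs * d).mean(axis=1)
        p = (np.sum(null >= obs) + 1) / (n_randomizations + 1)
        p_values[c] = p
        if p < 0.05:
            selected = c + 1
        else:
            break
    cv.selected = selected
    cv.p_values = p_values
    return selected


def bootstrap_errors(
    t: TrainingSet,
    fossil: CountMatrix,
    component: int,
    n_cycles: int = 1000,
    seed: int | None = None,
    sqrt_transform: bool = True,
) -> pd.DataFrame:
    """Sample-specific standard errors for a WA-PLS reconstruction.

    Training samples are resampled with replacement ``n_cycles`` times; the
    SE per fossil sample combines the across-bootstrap spread of its
    predictions (s1) with the root-mean-square out-of-bag training error
    (s2): SE = sqrt(s1^2 + s2^2).
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    rng = np.random.default_rng(seed)
    Y, taxa = _to_matrix(t.counts)
    cols = [str(i) for i in range(Y.shape[1])] if taxa is None else taxa
    n = Y.shape[0]
    fossil_df = pd.DataFrame(fossil.counts, columns=fossil.taxa)
    boot_preds = np.empty((n_cycles, fossil.n_samples))
    oob_sq: list[float] = []
    for b in range(n_cycles):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        sub = pd.DataFrame(Y[idx], columns=cols)
        m = WAPLS(n_components=component, sqrt_transform=sqrt_transform).fit(
            sub, t.climate[idx]
        )
        boot_preds[b] = m.predict(fossil_df, component=component)
        if oob.size:
            po = m.predict(pd.DataFrame(Y[oob], columns=cols), component=component)
            oob_sq.extend(((po - t.climate[oob]) ** 2).tolist())
    s1 = boot_preds.std(axis=0, ddof=1)
    s2 = float(np.sqrt(np.mean(oob_sq))) if oob_sq else 0.0
    return pd.DataFrame(
        {
            "sample_id": fossil.sample_ids,
            "estimate": boot_preds.mean(axis=0),
            "se": np.sqrt(s1**2 + s2**2),
            "s1": s1,
            "s2": s2,
        }
    )


# ---------------------------------------------------------------------------
# MAT


class MATRegressor(RegressorMixin, BaseEstimator):
    """Modern analogue technique under the chord distance.

    The k nearest modern spectra are the analogues; those with distance
    above ``threshold`` are rejected, and the prediction is the
    inverse-distance-weighted mean of the retained analogues' climate.  A
    zero-distance analogue returns its climate exactly.
    """

    def __init__(self, k: int = 6, threshold: float | None = None,
                 squared: bool = False):
        self.k = k
        self.threshold = threshold
        self.squared = squared

    def fit(self, X, y):
        Y, taxa = _to_matrix(X)
        if np.any(Y < 0):
            raise ValueError("negative abundance")
        if not 1 <= self.k <= Y.shape[0]:
            raise ValueError("k must be in [1, n_training_samples]")
        self.taxa_ = taxa
        self.train_props_ = _proportions(Y)
        self.climate_ = np.asarray(y, float)
        self.n_features_in_ = Y.shape[1]
        return self

    def analogue_table(self, X) -> pd.DataFrame:
        """Per-sample estimate, nearest distance, analogue count and flag."""
        check_is_fitted(self, "train_props_")
        F, fossil_taxa = _to_matrix(X)
        fi, mi = _match_taxa(
            fossil_taxa, self.taxa_ or list(range(self.n_features_in_)), F.shape[1]
        )
        sub = np.zeros((F.shape[0], self.n_features_in_))
        sub[:, mi] = F[:, fi]
        props = _proportions(sub)
        rows = []
        for i in range(props.shape[0]):
            if not np.all(np.isfinite(props[i])):
                rows.append((np.nan, np.nan, 0, True))
                continue
            d = chord_distance_matrix(
                props[i : i + 1], self.train_props_, squared=self.squared
            )[0]
            nearest = np.argsort(d, kind="stable")[: self.k]
            dk = d[nearest]
            if self.threshold is not None:
                keep = dk <= self.threshold
                nearest, dk = nearest[keep], dk[keep]
            if nearest.size == 0:
                rows.append((np.nan, float(d.min()), 0, True))
                continue
            if np.any(dk == 0):
                est = float(self.climate_[nearest[dk == 0]].mean())
            else:
                w = 1.0 / dk
                est = float(np.sum(w * self.climate_[nearest]) / w.sum())
            rows.append((est, float(dk.min()), int(nearest.size), False))
        return pd.DataFrame(
            rows, columns=["estimate", "min_distance", "n_analogues", "no_analogue"]
        )

    def predict(self, X) -> np.ndarray:
        return self.analogue_table(X)["estimate"].to_numpy()


def mat_reconstruct(
    t: TrainingSet,
    fossil: CountMatrix,
    k: int = 6,
    threshold: float | None = None,
    squared: bool = False,
) -> pd.DataFrame:
    m = MATRegressor(k=k, threshold=threshold, squared=squared).fit(
        t.counts, t.climate
    )
    out = m.analogue_table(fossil)
    out.insert(0, "sample_id", fossil.sample_ids)
    return out


def mat_threshold(
    t: TrainingSet,
    n_pairs: int = 1000,
    quantile: float = 0.05,
    seed: int | None = None,
    squared: bool = False,
) -> float:
    """Monte-Carlo no-analogue threshold: the given quantile of chord
    distances between random pairs of training samples."""
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100")
    n = t.counts.n_samples
    if n < 2:
        raise ValueError("need >= 2 training samples")
    rng = np.random.default_rng(seed)
    P = _proportions(np.asarray(t.counts.counts, float))
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct pairs
    diff = np.sqrt(P[i]) - np.sqrt(P[j])
    d = (diff**2).sum(axis=1)
    if not squared:
        d = np.sqrt(d)
    return float(np.quantile(d, quantile))


def reconstruction_significance(
    t: TrainingSet,
    fossil: CountMatrix,
    component: int,
    n_randomizations: int = 999,
    seed: int | None = None,
    sqrt_transform: bool = True,
) -> float:
    """Significance of a WA-PLS reconstruction against random environments.

    The statistic is the proportion of variance in the (transformed) fossil
    data explained by the reconstructed values; the null reconstructions
    come from models trained on permutations of the climate vector.
    p = (count of random >= real + 1) / (n + 1).
    """
    rng = np.random.default_rng(seed)
    Y, taxa = _to_matrix(t.counts)
    cols = [str(i) for i in range(Y.shape[1])] if taxa is None else taxa
    train_df = pd.DataFrame(Y, columns=cols)
    fossil_df = pd.DataFrame(fossil.counts, columns=fossil.taxa)
    F, f_taxa = _to_matrix(fossil)
    fi, mi = _match_taxa(f_taxa, cols, F.shape[1])
    sub = np.zeros((F.shape[0], len(cols)))
    sub[:, mi] = F[:, fi]
    Fp = _proportions(sub) * 100.0
    ok = np.all(np.isfinite(Fp), axis=1)
    Fp = np.sqrt(Fp[ok]) if sqrt_transform else Fp[ok]
    Fc = Fp - Fp.mean(axis=0)
    total_ss = float((Fc**2).sum())

    def explained(env: np.ndarray) -> float:
        m = WAPLS(n_components=component, sqrt_transform=sqrt_transform).fit(
            train_df, env
        )
        z = m.predict(fossil_df, component=component)[ok]
        zc = z - z.mean()
        denom = float(zc @ zc)
        if denom <= 0 or total_ss <= 0:
            return 0.0
        proj = (Fc.T @ zc) / denom  # per-taxon slope on the reconstruction
        return float(np.sum((np.outer(zc, proj)) ** 2)) / total_ss

    real = explained(t.climate)
    count = 0
    for _ in range(n_randomizations):
        if explained(rng.permutation(t.climate)) >= real:
            count += 1
    return (count + 1) / (n_randomizations + 1)
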