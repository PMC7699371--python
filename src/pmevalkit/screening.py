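"""Rollover screening and normalization selection for PM monitor data.

Saturated optical sensors can report *lower* values as the true concentration
keeps rising, so a monitor-vs-reference scatter bends back on itself (a
"half-circle": one reference value maps to two monitor values). Screening
fits a local regression to each experiment, flags curves that decline after
their maximum, takes each experiment's highest reliable monitor reading, and
pools the 10th percentile across experiments as the monitor's maximal
reliable concentration (in monitor-output units). Readings above the pooled
cutoff are removed.

The second screening task picks the normalization transform that makes the
concentration data closest to normal before linear (mixed) modelling. Each
candidate (identity, log10, sqrt, Box-Cox, Yeo-Johnson, ordered-quantile) is
scored by a cross-validated Pearson chi-square normality statistic divided by
its degrees of freedom; the lowest score wins. Cross-validation matters: the
rank-based ordered-quantile map is perfectly normal in-sample by
construction, so only out-of-fold scoring compares candidates fairly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CutoffReport",
    "TransformChoice",
    "FittedCurve",
    "TruncationResult",
    "loess",
    "smooth_experiment",
    "detect_negative_correlation",
    "pool_cutoff",
    "truncate",
    "select_normalization",
    "RolloverScreener",
    "NormalizationSelector",
]


def loess(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    span: float = 0.5,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights (loess).

    For each grid point the ``ceil(span * n)`` nearest observations are fit
    with a weighted degree-``degree`` polynomial; the fitted value at the
    grid point is returned. Degree 2 (local quadratic) is the default, as in
    base R's loess, and matters here: local-linear fits systematically
    undershoot at curve maxima, which is exactly where the rollover limit is
    read off.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = np.sort(x)
    grid = np.asarray(grid, float)
    n = x.size
    k = min(max(int(np.ceil(span * n)), degree + 2), n)
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argpartition(d, k - 1)[:k] if k < n else np.arange(n)
        dmax = d[idx].max()
        w = (1.0 - (d[idx] / (dmax if dmax > 0 else 1.0)) ** 3) ** 3
        X = np.vander(x[idx] - g, degree + 1, increasing=True)
        sw = np.sqrt(np.clip(w, 0.0, None))
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


class FittedCurve(NamedTuple):
    """Smoothed monitor response evaluated on a reference grid."""

    reference: np.ndarray
    fitted: np.ndarray
    observed_max: float  # highest raw monitor reading in the experiment


def smooth_experiment(
    reference: Sequence[float],
    monitor: Sequence[float],
    span: float = 0.5,
    degree: int = 2,
    grid_size: int = 200,
    min_points: int = 20,
) -> FittedCurve | None:
    """Loess fit of monitor output against the reference concentration.

    Returns None (with a warning) when fewer than ``min_points`` pairs are
    available, mirroring skipping short experiments.
    """
    ref = np.asarray(reference, float)
    mon = np.asarray(monitor, float)
    ok = np.isfinite(ref) & np.isfinite(mon)
    ref, mon = ref[ok], mon[ok]
    if ref.size < min_points:
        warnings.warn(
            f"experiment skipped: only {ref.size} paired points (< {min_points})",
            stacklevel=2,
        )
        return None
    grid = np.linspace(ref.min(), ref.max(), grid_size)
    fitted = loess(ref, mon, grid, span=span, degree=degree)
    return FittedCurve(grid, fitted, float(mon.max()))


def detect_negative_correlation(
    curve: FittedCurve, decline_tol: float = 0.05
) -> tuple[bool, float]:
    """Flag a rollover and report the experiment's reliable-reading limit.

    The curve is flagged when the fitted monitor value falls more than
    ``decline_tol`` times its maximum after that maximum while the reference
    keeps increasing. The limit is the maximum fitted reading before the
    decline when flagged, otherwise the maximum observed monitor reading.
    Both are in monitor-output units. Invariant to rescaling both axes.
    """
    fitted = np.asarray(curve.fitted, float)
    apex_idx = int(np.nanargmax(fitted))
    apex = fitted[apex_idx]
    post = fitted[apex_idx:]
    decline = apex - np.nanmin(post) if post.size else 0.0
    flagged = apex > 0 and decline > decline_tol * apex
    limit = float(apex) if flagged else float(curve.observed_max)
    return flagged, limit


@dataclass(frozen=True)
class CutoffReport:
    """Pooled rollover cutoff for one monitor unit (or type)."""

    unit_id: str
    n_experiments: int
    n_flagged: int
    per_experiment_limits: tuple[float, ...]  # monitor-output ug/m^3
    cutoff: float | None  # monitor-output ug/m^3; None if too few flags
    flag_fraction: float = 0.10
    percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.n_flagged > self.n_experiments:
            raise ValueError("n_flagged cannot exceed n_experiments")


def pool_cutoff(
    limits: Sequence[float],
    flags: Sequence[bool],
    flag_fraction: float = 0.10,
    percentile: float = 10.0,
    unit_id: str = "",
) -> CutoffReport:
    """Pool per-experiment limits into a maximal reliable concentration.

    When the share of flagged experiments reaches ``flag_fraction`` (10%:
    only structural miscorrelations, not outliers), the cutoff is the
    ``percentile``-th percentile (linear interpolation between order
    statistics, type 7) of all pooled per-experiment limits; otherwise no
    cutoff is set.
    """
    limits = tuple(float(v) for v in limits)
    flags = [bool(f) for f in flags]
    if not limits or len(limits) != len(flags):
        raise ValueError("need paired, non-empty limits and flags")
    n_flagged = sum(flags)
    share = n_flagged / len(flags)
    cutoff = float(np.percentile(limits, percentile)) if share >= flag_fraction else None
    return CutoffReport(
        unit_id=unit_id,
        n_experiments=len(limits),
        n_flagged=n_flagged,
        per_experiment_limits=limits,
        cutoff=cutoff,
        flag_fraction=flag_fraction,
        percentile=percentile,
    )


class TruncationResult(NamedTuple):
    series: np.ndarray
    removed_count: int
    mask: np.ndarray  # True where retained


def truncate(series: Sequence[float], cutoff: float | None) -> TruncationResult:
    """Drop monitor readings above the cutoff (identity when cutoff is None)."""
    values = np.asarray(series, float)
    if cutoff is None:
        return TruncationResult(values, 0, np.ones(values.size, bool))
    mask = values <= cutoff
    kept = values[mask]
    if kept.size == 0 and values.size:
        warnings.warn("all readings above cutoff; empty series returned", stacklevel=2)
    return TruncationResult(kept, int(values.size - kept.size), mask)


# --------------------------------------------------------------------------
# normalization transform selection


@dataclass(frozen=True)
class TransformChoice:
    """A fitted normalization transform and its normality score."""

    name: str
    parameters: dict = field(default_factory=dict)
    normality_score: float = np.nan

    def transform(self, values):
        v = np.asarray(values, float)
        p = self.parameters
        if self.name == "identity":
            return v
        if self.name == "log10":
            return np.log10(v + p.get("offset", 0.0))
        if self.name == "sqrt":
            return np.sqrt(v)
        if self.name == "box-cox":
            lam = p["lambda"]
            shifted = v + p.get("offset", 0.0)
            return np.log(shifted) if lam == 0 else (shifted**lam - 1.0) / lam
        if self.name == "yeo-johnson":
            return stats.yeojohnson(v, lmbda=p["lambda"])
        if self.name == "ordered-quantile":
            ref = np.asarray(p["reference_values"])
            scores = np.asarray(p["normal_scores"])
            return np.interp(v, ref, scores)
        raise ValueError(f"unknown transform {self.name!r}")

    def inverse(self, values):
        v = np.asarray(values, float)
        p = self.parameters
        if self.name == "identity":
            return v
        if self.name == "log10":
            return np.power(10.0, v) - p.get("offset", 0.0)
        if self.name == "sqrt":
            return v**2
        if self.name == "box-cox":
            lam = p["lambda"]
            shifted = np.exp(v) if lam == 0 else np.power(lam * v + 1.0, 1.0 / lam)
            return shifted - p.get("offset", 0.0)
        if self.name == "yeo-johnson":
            lam = p["lambda"]
            out = np.empty_like(v)
            pos = v >= 0
            if lam != 0:
                out[pos] = np.power(v[pos] * lam + 1.0, 1.0 / lam) - 1.0
            else:
                out[pos] = np.expm1(v[pos])
            if lam != 2:
                out[~pos] = 1.0 - np.power(1.0 - (2.0 - lam) * v[~pos], 1.0 / (2.0 - lam))
            else:
                out[~pos] = -np.expm1(-v[~pos])
            return out
        if self.name == "ordered-quantile":
            ref = np.asarray(p["reference_values"])
            scores = np.asarray(p["normal_scores"])
            return np.interp(v, scores, ref)
        raise ValueError(f"unknown transform {self.name!r}")


CANDIDATE_TRANSFORMS = ("identity", "log10", "sqrt", "box-cox", "yeo-johnson", "ordered-quantile")


def _fit_transform(name: str, train: np.ndarray) -> TransformChoice:
    """Fit one candidate transform's parameters on training values."""
    params: dict = {}
    if name in ("log10", "box-cox"):
        if np.any(train <= 0):
            positive = train[train > 0]
            if positive.size == 0:
                raise ValueError(f"{name} transform needs some positive values")
            params["offset"] = float(positive.min() / 2.0)
    if name == "box-cox":
        _, lam = stats.boxcox(train + params.get("offset", 0.0))
        params["lambda"] = float(lam)
    elif name == "yeo-johnson":
        _, lam = stats.yeojohnson(train)
        params["lambda"] = float(lam)
    elif name == "ordered-quantile":
        srt = np.sort(train)
        n = srt.size
        scores = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        params["reference_values"] = srt
        params["normal_scores"] = scores
    return TransformChoice(name, params)


def pearson_normality_stat(values: np.ndarray) -> float:
    """Pearson chi-square normality statistic divided by degrees of freedom.

    The standardized sample is classified into ``ceil(2 * n^0.4)``
    equiprobable normal classes; the statistic is the usual sum of
    (observed - expected)^2 / expected, divided by (classes - 3) degrees of
    freedom (two parameters estimated). Lower is more normal.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 8:
        raise ValueError("too few values for a normality statistic")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; normality statistic undefined")
    z = (v - v.mean()) / sd
    k = int(np.ceil(2.0 * n**0.4))
    edges = stats.norm.ppf(np.arange(1, k) / k)
    observed = np.bincount(np.searchsorted(edges, z), minlength=k)
    expected = n / k
    chi2 = float(np.sum((observed - expected) ** 2) / expected)
    return chi2 / max(k - 3, 1)


def select_normalization(
    values: Sequence[float],
    candidates: Sequence[str] = CANDIDATE_TRANSFORMS,
    n_folds: int = 10,
    seed: int = 0,
) -> TransformChoice:
    """Pick the transform whose out-of-fold output is closest to normal.

    Each candidate is fitted on the training folds and scored on the held-out
    fold with the Pearson chi-square statistic per degree of freedom; fold
    scores are averaged. The lowest mean score wins; near-degenerate ties are
    broken by candidate order (identity first, log10 second). The winning
    transform is refitted on the full sample.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 30:
        raise ValueError("normalization selection requires n >= 30")
    if np.ptp(v) == 0:
        raise ValueError("constant sample; no transform can normalize it")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(v.size)
    folds = [perm[i::n_folds] for i in range(n_folds)]

    scores: dict[str, float] = {}
    for name in candidates:
        fold_scores = []
        try:
            for hold in folds:
                train_mask = np.ones(v.size, bool)
                train_mask[hold] = False
                tc = _fit_transform(name, v[train_mask])
                fold_scores.append(pearson_normality_stat(tc.transform(v[hold])))
            scores[name] = float(np.mean(fold_scores))
        except (ValueError, FloatingPointError):
            continue  # candidate not applicable to this sample
    if not scores:
        raise ValueError("no candidate transform applicable to this sample")

    best = min(scores, key=lambda name: (scores[name], candidates.index(name)))
    chosen = _fit_transform(best, v)
    return TransformChoice(best, chosen.parameters, scores[best])


# --------------------------------------------------------------------------
# estimator-style wrappers


class RolloverScreener(BaseEstimator):
    """Detect rollover across experiments and pool the reliable-reading cutoff.

    Parameters mirror the screening operations: loess ``span`` and
    ``degree``, the post-apex ``decline_tol`` (fraction of the apex), the
    ``flag_fraction`` of experiments required before a cutoff is set, and the
    pooled ``percentile``.
    """

    def __init__(
        self,
        span: float = 0.5,
        degree: int = 2,
        decline_tol: float = 0.05,
        flag_fraction: float = 0.10,
        percentile: float = 10.0,
        min_points: int = 20,
    ):
        self.span = span
        self.degree = degree
        self.decline_tol = decline_tol
        self.flag_fraction = flag_fraction
        self.percentile = percentile
        self.min_points = min_points

    def fit(self, X, y=None, unit_id: str = ""):
        """X: sequence of (reference, monitor) array pairs, one per experiment."""
        limits, flags = [], []
        for ref, mon in X:
            curve = smooth_experiment(
                ref, mon, span=self.span, degree=self.degree, min_points=self.min_points
            )
            if curve is None:
                continue
            flag, limit = detect_negative_correlation(curve, self.decline_tol)
            limits.append(limit)
            flags.append(flag)
        if not limits:
            raise ValueError("no experiment had enough points to screen")
        self.report_ = pool_cutoff(
            limits, flags, self.flag_fraction, self.percentile, unit_id=unit_id
        )
        self.limits_ = np.asarray(limits)
        self.flags_ = np.asarray(flags)
        self.cutoff_ = self.report_.cutoff
        return self

    def transform(self, series):
        """Truncate a monitor series at the pooled cutoff."""
        if not hasattr(self, "cutoff_"):
            raise AttributeError("RolloverScreener is not fitted")
        return truncate(series, self.cutoff_)


class NormalizationSelector(BaseEstimator):
    """sklearn-style wrapper over select_normalization (fit/transform/inverse)."""

    def __init__(self, candidates: Sequence[str] = CANDIDATE_TRANSFORMS,
                 n_folds: int = 10, seed: int = 0):
        self.candidates = candidates
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X, y=None):
        self.choice_ = select_normalization(
            np.asarray(X, float).ravel(), self.candidates, self.n_folds, self.seed
        )
        return self

    def transform(self, X):
        return self.choice_.transform(X)

    def inverse_transform(self, X):
        return self.choice_.inverse(X)
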