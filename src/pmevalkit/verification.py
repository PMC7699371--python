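"""Bin-wise accuracy verification: bias, precision, relative uncertainty.

Accuracy is quantified as a symmetric 95% band around the reference,

    uncertainty (%) = (|B| + 1.96 * S) * 100,

where within each concentration bin B is the mean relative bias of the
corrected monitor readings, and S is the relative precision after removing
the reference instrument's own uncertainty in quadrature:

    B = mean((pred - ref) / ref),
    S = sqrt(max(SD(pred / ref)^2 - s_ref^2 - s_extra^2, 0)),

with s_ref = 0.10 (the APS manufacturer uncertainty) and s_extra an optional
additional variance term for exposure instability (default 0). Bias and
precision are only homogeneous over narrow concentration ranges, so the
verification set is split into bins of the reference concentration (default
uppers 500/1000/1500/2000/3000/5000 ug/m^3); bins with fewer than ``n_min``
pairs are reported as not available.

The value of correcting for evaluation variables is measured by the per-bin
ratio of the uncertainty of a reduced model (base regression only, an
"average correction") to the full model; a mean fold ratio above 1 means the
evaluation variables bought accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BIN_EDGES",
    "UncertaintyBin",
    "UncertaintyReport",
    "FoldComparison",
    "bin_by_reference",
    "bias_precision",
    "relative_uncertainty",
    "uncertainty_report",
    "compare_corrections",
]

DEFAULT_BIN_EDGES = (0.0, 500.0, 1000.0, 1500.0, 2000.0, 3000.0, 5000.0)
DEFAULT_REF_UNCERTAINTY = 0.10


@dataclass(frozen=True)
class UncertaintyBin:
    """Accuracy summary for one concentration bin [lower, upper)."""

    lower: float
    upper: float
    n: int
    bias: float  # relative, dimensionless
    precision: float  # relative SD, dimensionless
    uncertainty: float  # %
    meets_target: bool
    status: str  # "ok" | "insufficient_data"

    def __post_init__(self) -> None:
        if self.status == "ok" and (self.precision < 0 or self.uncertainty < 0):
            raise ValueError("precision and uncertainty must be >= 0")


class FoldComparison(NamedTuple):
    per_bin: dict[tuple[float, float], float]  # uncertainty_reduced / uncertainty_full
    average: float
    excluded_bins: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class UncertaintyReport:
    """Bin-wise verification of one monitor plus optional fold comparison."""

    monitor: str
    bins: tuple[UncertaintyBin, ...]
    overall_range_uncertainty: float  # % over all binned pairs together
    comparison: FoldComparison | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "upper_ugm3": [b.upper for b in self.bins],
                "n": [b.n for b in self.bins],
                "bias": [b.bias for b in self.bins],
                "precision": [b.precision for b in self.bins],
                "uncertainty_pct": [b.uncertainty for b in self.bins],
                "meets_target": [b.meets_target for b in self.bins],
                "status": [b.status for b in self.bins],
            }
        )


def bin_by_reference(
    predictions: Sequence[float],
    reference: Sequence[float],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], int]:
    """Assign (prediction, reference) pairs to half-open bins [lower, upper).

    Binning is on the reference (true-side) concentration. Pairs at or above
    the last edge are excluded; their count is returned alongside the binned
    pairs.
    """
    pred = np.asarray(predictions, float)
    ref = np.asarray(reference, float)
    if pred.size != ref.size:
        raise ValueError("predictions and reference must be paired")
    edges = np.asarray(edges, float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    idx = np.searchsorted(edges, ref, side="right") - 1
    inside = (idx >= 0) & (ref < edges[-1])
    excluded = int(np.sum(~inside))
    binned = []
    for b in range(edges.size - 1):
        m = inside & (idx == b)
        binned.append((pred[m], ref[m]))
    return binned, excluded


def bias_precision(
    predictions: Sequence[float],
    reference: Sequence[float],
    ref_uncertainty: float = DEFAULT_REF_UNCERTAINTY,
    extra_sd: float = 0.0,
    n_min: int = 30,
) -> tuple[float, float, int, str]:
    """Relative bias and reference-deconvolved precision for one bin.

    Returns ``(bias, precision, n, status)``; when fewer than ``n_min`` pairs
    are available the status is "insufficient_data" and bias/precision are
    NaN. Reference values must be positive (zero-concentration samples carry
    no relative-error information and must be excluded upstream).
    """
    pred = np.asarray(predictions, float)
    ref = np.asarray(reference, float)
    n = int(pred.size)
    if n < n_min:
        return np.nan, np.nan, n, "insufficient_data"
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive for relative errors")
    ratio = pred / ref
    bias = float(np.mean(ratio - 1.0))
    s_obs = float(np.std(ratio, ddof=1))
    s_monitor = float(np.sqrt(max(s_obs**2 - ref_uncertainty**2 - extra_sd**2, 0.0)))
    return bias, s_monitor, n, "ok"


def relative_uncertainty(bias: float, precision: float) -> float:
    """Symmetric 95% accuracy band combining bias and precision, in percent."""
    if not np.isfinite(bias):
        return np.nan
    if precision < 0:
        raise ValueError("precision must be >= 0")
    return (abs(bias) + 1.96 * precision) * 100.0


def uncertainty_report(
    predictions: Sequence[float],
    reference: Sequence[float],
    monitor: str = "",
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    ref_uncertainty: float = DEFAULT_REF_UNCERTAINTY,
    extra_sd: float = 0.0,
    n_min: int = 30,
    target: float = 50.0,
) -> UncertaintyReport:
    """Bin-wise bias/precision/uncertainty table for one monitor."""
    binned, _ = bin_by_reference(predictions, reference, edges)
    bins = []
    for (lo, hi), (pred, ref) in zip(zip(edges[:-1], edges[1:]), binned):
        bias, prec, n, status = bias_precision(pred, ref, ref_uncertainty, extra_sd, n_min)
        unc = relative_uncertainty(bias, prec) if status == "ok" else np.nan
        bins.append(
            UncertaintyBin(
                lower=float(lo),
                upper=float(hi),
                n=n,
                bias=bias,
                precision=prec,
                uncertainty=unc,
                meets_target=bool(status == "ok" and unc <= target),
                status=status,
            )
        )
    all_pred = np.concatenate([p for p, _ in binned])
    all_ref = np.concatenate([r for _, r in binned])
    bias, prec, n, status = bias_precision(all_pred, all_ref, ref_uncertainty, extra_sd, n_min)
    overall = relative_uncertainty(bias, prec) if status == "ok" else np.nan
    return UncertaintyReport(monitor=monitor, bins=tuple(bins), overall_range_uncertainty=overall)


def compare_corrections(
    full_predictions: Sequence[float],
    reduced_predictions: Sequence[float],
    reference: Sequence[float],
    monitor: str = "",
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    ref_uncertainty: float = DEFAULT_REF_UNCERTAINTY,
    extra_sd: float = 0.0,
    n_min: int = 30,
    target: float = 50.0,
) -> tuple[UncertaintyReport, UncertaintyReport, FoldComparison]:
    """Per-bin uncertainty of the full vs the reduced ("average") correction.

    Both prediction sets must come from models trained on the same screening
    data and evaluated on the same verification pairs. The fold for a bin is
    uncertainty_reduced / uncertainty_full; bins undefined (insufficient
    data, or zero uncertainty in the full model) in either report are
    excluded from the average.
    """
    full = uncertainty_report(
        full_predictions, reference, monitor, edges, ref_uncertainty, extra_sd, n_min, target
    )
    reduced = uncertainty_report(
        reduced_predictions, reference, monitor, edges, ref_uncertainty, extra_sd, n_min, target
    )
    per_bin: dict[tuple[float, float], float] = {}
    excluded = []
    for bf, br in zip(full.bins, reduced.bins):
        key = (bf.lower, bf.upper)
        if bf.status != "ok" or br.status != "ok" or bf.uncertainty == 0:
            excluded.append(key)
            continue
        per_bin[key] = br.uncertainty / bf.uncertainty
    average = float(np.mean(list(per_bin.values()))) if per_bin else np.nan
    comparison = FoldComparison(per_bin, average, tuple(excluded))
    return (
        UncertaintyReport(full.monitor, full.bins, full.overall_range_uncertainty, comparison),
        reduced,
        comparison,
    )
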