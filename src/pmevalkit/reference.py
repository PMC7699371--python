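"""Reference-instrument processing: size bins to mass, calibration, checks.

An aerodynamic particle sizer (APS) counts particles per aerodynamic-diameter
bin. Converting counts to a mass concentration for a non-spherical dust needs
the material density rho and dynamic shape factor chi: the volume-equivalent
diameter is

    d_ve = d_aero * sqrt(chi * rho0 / rho),    rho0 = 1 g/cm^3,

and the per-particle mass is rho * (pi/6) * d_ve^3. Size-selective fractions
are applied as weights: an indicator d <= 2.5 um for PM2.5, the ISO 7708
respirable convention (cumulative log-normal, median 4.25 um, GSD 1.5) for
the respirable fraction.

The real-time APS is calibrated against time-averaged gravimetric samples
(the gold standard) with an ordinary least-squares line; the correction is
the inverse mapping applied to real-time readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .chamber import MaterialProperties

__all__ = [
    "SizeBinSample",
    "ReferenceCalibration",
    "InvarianceResult",
    "SpatialSummary",
    "respirable_weight",
    "bins_to_mass",
    "calibrate_reference",
    "invariance_check",
    "spatial_medians",
    "average_over_windows",
]

#: ISO 7708 respirable convention parameters (cumulative log-normal form).
RESPIRABLE_MEDIAN_UM = 4.25
RESPIRABLE_GSD = 1.5


@dataclass(frozen=True)
class SizeBinSample:
    """Particle counts per aerodynamic-diameter bin for one sampling interval."""

    bin_mid_diameter: np.ndarray  # um aerodynamic, strictly increasing
    counts: np.ndarray  # particles per bin
    sample_volume: float  # cm^3
    duration: float | None = None  # s

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_mid_diameter, float)
        c = np.asarray(self.counts, float)
        object.__setattr__(self, "bin_mid_diameter", d)
        object.__setattr__(self, "counts", c)
        if d.size != c.size:
            raise ValueError("diameters and counts must have equal length")
        if d.size and not np.all(np.diff(d) > 0):
            raise ValueError("bin diameters must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        if self.sample_volume <= 0:
            raise ValueError("sample_volume must be positive")


def respirable_weight(d_aero) -> np.ndarray | float:
    """ISO 7708 respirable-convention weight for aerodynamic diameter(s) in um.

    Survival function of a log-normal with median 4.25 um and geometric
    standard deviation 1.5: 1 at d = 0, 0.5 at the convention median,
    essentially 0 beyond ~15 um. Monotonically non-increasing in d.
    """
    d = np.asarray(d_aero, float)
    if np.any(d < 0):
        raise ValueError("aerodynamic diameter must be >= 0")
    with np.errstate(divide="ignore"):
        z = np.where(d > 0, np.log(np.where(d > 0, d, 1.0) / RESPIRABLE_MEDIAN_UM), -np.inf)
    w = stats.norm.sf(z / np.log(RESPIRABLE_GSD))
    return float(w) if np.isscalar(d_aero) else w


def bins_to_mass(
    sample: SizeBinSample,
    material: MaterialProperties,
    fraction: str = "respirable",
    shape_mode: str = "diameter",
) -> float:
    """Mass concentration (ug/m^3) from a size-bin sample.

    ``fraction`` is one of "pm25" (indicator d_aero <= 2.5 um), "respirable"
    (ISO 7708 weight) or "total". ``shape_mode`` selects where the dynamic
    shape factor enters: "diameter" converts aerodynamic to volume-equivalent
    diameter (d_ve = d_aero * sqrt(chi rho0 / rho), the default) while "mass"
    multiplies the uncorrected spherical mass by chi directly.

    With diameters in um, density in g/cm^3 and volume in cm^3, the unit
    factors cancel to give ug/m^3 directly:
    counts * rho * (pi/6) * d_um^3 / volume_cm3.
    """
    if fraction not in ("pm25", "respirable", "total"):
        raise ValueError(f"unknown fraction {fraction!r}")
    if shape_mode not in ("diameter", "mass"):
        raise ValueError(f"unknown shape_mode {shape_mode!r}")
    d = sample.bin_mid_diameter
    if d.size == 0 or np.all(sample.counts == 0):
        if d.size == 0:
            warnings.warn("empty size-bin sample; returning zero mass", stacklevel=2)
        return 0.0

    if shape_mode == "diameter":
        d_ve = d * np.sqrt(material.shape_factor * 1.0 / material.density)
        per_particle = material.density * (np.pi / 6.0) * d_ve**3
    else:
        # spherical (chi = 1) density conversion, then chi applied to mass
        d_ve = d * np.sqrt(1.0 / material.density)
        per_particle = material.shape_factor * material.density * (np.pi / 6.0) * d_ve**3

    if fraction == "pm25":
        w = (d <= 2.5).astype(float)
    elif fraction == "respirable":
        w = respirable_weight(d)
    else:
        w = np.ones_like(d)
    return float(np.sum(sample.counts * per_particle * w) / sample.sample_volume)


@dataclass(frozen=True)
class ReferenceCalibration:
    """OLS line relating real-time APS averages to gravimetric samples.

    The fitted model is ``aps = intercept + slope * gravimetric``; correcting
    a real-time reading applies the inverse mapping
    ``(reading - intercept) / slope``.
    """

    slope: float
    intercept: float  # ug/m^3
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def correct(self, readings):
        """Map real-time reference readings onto the gravimetric scale."""
        return (np.asarray(readings, float) - self.intercept) / self.slope


def calibrate_reference(
    aps_averages: Sequence[float], gravimetric: Sequence[float]
) -> ReferenceCalibration:
    """Fit the APS-vs-gravimetric calibration line (>= 3 paired averages)."""
    aps = np.asarray(aps_averages, float)
    grav = np.asarray(gravimetric, float)
    if aps.size != grav.size:
        raise ValueError("aps_averages and gravimetric must be paired")
    if aps.size < 3:
        raise ValueError("calibration requires at least 3 pairs")
    if np.ptp(grav) == 0:
        raise ValueError("gravimetric values are constant; cannot calibrate")
    if np.ptp(aps) == 0:
        raise ValueError("APS values are constant; cannot calibrate")
    res = stats.linregress(grav, aps)
    return ReferenceCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


class InvarianceResult(NamedTuple):
    """Slope and R^2 of varied-condition readings vs default-condition expectation."""

    slope: float
    r_squared: float


def invariance_check(
    calibrated_default: tuple[Sequence[float], Sequence[float]],
    calibrated_varied: tuple[Sequence[float], Sequence[float]],
) -> InvarianceResult:
    """Check that the reference is insensitive to the evaluation variables.

    Both arguments are ``(gravimetric, aps_average)`` pairs. A calibration
    is fitted on the default-condition set; the varied-condition APS values
    are regressed on the expectation predicted by that calibration. A slope
    near 1 with high R^2 says temperature/humidity/pattern changes do not
    move the reference.
    """
    grav_d, aps_d = (np.asarray(v, float) for v in calibrated_default)
    grav_v, aps_v = (np.asarray(v, float) for v in calibrated_varied)
    cal = calibrate_reference(aps_d, grav_d)
    expected = cal.intercept + cal.slope * grav_v
    if np.ptp(expected) == 0:
        raise ValueError("default-condition expectation is constant")
    res = stats.linregress(expected, aps_v)
    return InvarianceResult(float(res.slope), float(res.rvalue**2))


class SpatialSummary(NamedTuple):
    medians: dict[str, float]  # ug/m^3 per location
    max_min_ratio: float


def spatial_medians(series_by_location: Mapping[str, Sequence[float]]) -> SpatialSummary:
    """Median concentration per chamber location plus the max/min ratio."""
    if len(series_by_location) < 2:
        raise ValueError("spatial check needs at least 2 locations")
    med = {loc: float(np.median(np.asarray(v, float))) for loc, v in series_by_location.items()}
    vals = list(med.values())
    return SpatialSummary(med, max(vals) / min(vals))


def average_over_windows(
    times: Sequence[float],
    values: Sequence[float],
    windows: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Time-average a real-time series over gravimetric sampling windows.

    Each window is ``(start, end)``; samples with start <= t < end are
    averaged. Windows containing no samples yield NaN.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    out = np.full(len(windows), np.nan)
    for i, (a, b) in enumerate(windows):
        mask = (t >= a) & (t < b)
        if mask.any():
            out[i] = v[mask].mean()
    return out
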