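"""Synthetic chamber experiments for low-cost PM monitor evaluation.

This module generates seeded exposure-chamber datasets with the statistical
structure the downstream evaluation assumes: plateau ("stable") and peak
("transient") concentration profiles, a real-time reference instrument with
multiplicative relative noise, and low-cost monitors whose response depends on
the test material, temperature, relative humidity, power supply, exposure
pattern, per-unit manufacturing variation, session-to-session drift, and an
optional high-concentration rollover above which the expected reading declines
(the "half-circle" artifact of saturated optical sensors).

All effects enter the sensor model on the log scale,

    log G = log(base_gain * material_gain)
            + temp_slope * (T - 20) + rh_slope * (RH - 50)
            + power_shift * 1{battery} + pattern_shift * 1{transient}
            + drift_slope * session_time + u,   u ~ Normal(0, device_sd^2),

and readings are ``true * G`` times mean-one log-normal noise, so simulated
concentrations stay positive and the per-unit effect ``u`` is reproducible
across experiments (it is keyed on the unit label and the root seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MaterialProperties",
    "ConditionSet",
    "SensorResponseSpec",
    "ExperimentSeries",
    "Profile",
    "DEFAULT_MATERIALS",
    "DEFAULT_LEVELS",
    "profile_stable",
    "profile_transient",
    "simulate_experiment",
    "build_design",
    "simulate_design",
    "expected_monitor_response",
    "resample_series",
    "experiments_to_frame",
    "write_experiments",
]


@dataclass(frozen=True)
class MaterialProperties:
    """Physical and optical properties of a chamber test dust.

    ``monitor_gain`` is the multiplicative response factor of an optical
    monitor to this material (refractive index, shape and density all fold
    into it); it is the generative counterpart of the material random effect
    in the correction model.
    """

    name: str
    density: float  # g/cm^3
    shape_factor: float = 1.5  # dynamic shape factor, dimensionless
    monitor_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.shape_factor < 1:
            raise ValueError("shape_factor must be >= 1")
        if self.monitor_gain <= 0:
            raise ValueError("monitor_gain must be positive")


#: The three test dusts: Arizona Road Dust, quartz and aluminium oxide, all
#: with dynamic shape factor 1.5 and densities 2.6, 2.6 and 3.95 g/cm^3.
#: Monitor gains are the synthetic study conditions: a strongly scattering
#: material (quartz), a weak one (alumina) and ARD as the 1.0 anchor.
DEFAULT_MATERIALS: dict[str, MaterialProperties] = {
    "ard": MaterialProperties("ard", density=2.6, shape_factor=1.5, monitor_gain=1.0),
    "quartz": MaterialProperties("quartz", density=2.6, shape_factor=1.5, monitor_gain=1.3),
    "alumina": MaterialProperties("alumina", density=3.95, shape_factor=1.5, monitor_gain=0.7),
}

#: Evaluation-variable levels; the first entry of each list is the default arm
#: (battery power, 20 degC, 50% RH, transient pattern, session 0).
DEFAULT_LEVELS: dict[str, list] = {
    "material": ["ard", "quartz", "alumina"],
    "temperature": [20.0, 15.0, 25.0],
    "relative_humidity": [50.0, 25.0, 75.0],
    "power": ["battery", "wired"],
    "pattern": ["transient", "stable"],
    "session_time": [0.0, 24.0, 48.0],
}


@dataclass(frozen=True)
class ConditionSet:
    """Evaluation-variable levels attached to one chamber experiment."""

    material: str = "ard"
    temperature: float = 20.0  # degC
    relative_humidity: float = 50.0  # %
    power: str = "battery"
    pattern: str = "transient"
    session_time: float = 0.0  # hours since first session
    unit_id: tuple[str, ...] = ("u1",)
    location_tag: str = "middle"

    def __post_init__(self) -> None:
        if isinstance(self.unit_id, str):
            object.__setattr__(self, "unit_id", (self.unit_id,))
        else:
            object.__setattr__(self, "unit_id", tuple(self.unit_id))
        if self.power not in ("battery", "wired"):
            raise ValueError(f"unknown power supply {self.power!r}")
        if self.pattern not in ("stable", "transient"):
            raise ValueError(f"unknown exposure pattern {self.pattern!r}")
        if self.session_time < 0:
            raise ValueError("session_time must be >= 0")


@dataclass(frozen=True)
class SensorResponseSpec:
    """Generative response model of one low-cost monitor type.

    Slopes act on log gain; ``noise_cv`` is the coefficient of variation of
    the mean-one multiplicative reading noise; ``rollover_limit`` is the true
    concentration (ug/m^3) above which the expected response declines, with
    decline slope ``rollover_slope`` (defaults to the pre-rollover slope,
    giving a symmetric tent and hence the half-circle monitor-vs-reference
    scatter).
    """

    base_gain: float = 1.0
    temp_slope: float = 0.002  # per degC
    rh_slope: float = 0.0005  # per % RH
    power_shift: float = 0.01  # applies when battery powered
    pattern_shift: float = 0.08  # applies to transient exposures
    device_sd: float = 0.02  # SD of per-unit log-gain effect
    drift_slope: float = 0.0002  # per hour of session time
    noise_cv: float = 0.05
    rollover_limit: float | None = None  # ug/m^3 true concentration
    rollover_slope: float | None = None  # decline per ug/m^3; None -> symmetric

    def __post_init__(self) -> None:
        if self.base_gain <= 0:
            raise ValueError("base_gain must be positive")
        if self.noise_cv < 0 or self.device_sd < 0:
            raise ValueError("noise_cv and device_sd must be >= 0")
        if self.rollover_limit is not None and self.rollover_limit <= 0:
            raise ValueError("rollover_limit must be positive when present")


class Profile(NamedTuple):
    """A latent true-concentration trace (seconds, ug/m^3)."""

    time: np.ndarray
    concentration: np.ndarray
    pattern: str


@dataclass
class ExperimentSeries:
    """One chamber experiment: aligned monitor and reference time series.

    ``true_concentration`` is the latent trace, retained for testing only;
    ``monitor_readings`` has one column per unit in ``conditions.unit_id``.
    """

    time: np.ndarray
    true_concentration: np.ndarray
    reference_reading: np.ndarray
    monitor_readings: pd.DataFrame
    conditions: ConditionSet
    gravimetric_value: float | None = None
    experiment_id: str = ""
    arm: str = "default"  # which screening variable this experiment varies

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.reference_reading < 0) or np.any(self.true_concentration < 0):
            raise ValueError("concentrations must be >= 0")
        if set(self.monitor_readings.columns) != set(self.conditions.unit_id):
            raise ValueError("monitor columns must match conditions.unit_id")

    def to_frame(self) -> pd.DataFrame:
        """Wide per-experiment table (time_s, true, reference, one col/unit)."""
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "true_ugm3": self.true_concentration,
                "reference_ugm3": self.reference_reading,
            }
        )
        for unit in self.monitor_readings.columns:
            df[unit] = self.monitor_readings[unit].to_numpy()
        return df


def profile_stable(
    levels: Sequence[float],
    plateau_duration: float = 900.0,
    ramp_fraction: float = 0.1,
    dt: float = 15.0,
) -> Profile:
    """Piecewise plateau profile visiting each level with linear ramps.

    Each plateau lasts ``plateau_duration`` seconds (>= 15 min by default);
    consecutive plateaus are joined by a ramp of ``ramp_fraction *
    plateau_duration`` seconds. Within-plateau means equal the requested
    levels exactly.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("at least one concentration level is required")
    if any(lv <= 0 for lv in levels):
        raise ValueError("levels must be positive")
    if plateau_duration <= 0 or dt <= 0:
        raise ValueError("durations must be positive")

    n_plat = max(int(round(plateau_duration / dt)), 1)
    n_ramp = int(round(ramp_fraction * plateau_duration / dt))
    segments: list[np.ndarray] = []
    for i, lv in enumerate(levels):
        segments.append(np.full(n_plat, float(lv)))
        if i < len(levels) - 1 and n_ramp > 0:
            # interior ramp samples, endpoints belong to the plateaus
            frac = np.arange(1, n_ramp + 1) / (n_ramp + 1)
            segments.append(lv + (levels[i + 1] - lv) * frac)
    conc = np.concatenate(segments)
    grid = np.arange(conc.size) * dt
    return Profile(grid, conc, "stable")


def profile_transient(
    peak_max: float = 5000.0,
    peak_duration: float = 1800.0,
    n_peaks: int = 3,
    dt: float = 15.0,
    shape: str = "linear",
) -> Profile:
    """Repeated 0 -> peak_max -> 0 excursions ("peaks"), 30 min each by default.

    ``shape`` is "linear" (triangular) or "exponential" (convex rise/decay);
    the global maximum is exactly ``peak_max``.
    """
    if peak_max < 0:
        raise ValueError("peak_max must be >= 0")
    if peak_duration <= 0 or dt <= 0:
        raise ValueError("durations must be positive")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if shape not in ("linear", "exponential"):
        raise ValueError("shape must be 'linear' or 'exponential'")

    half = peak_duration / 2.0
    t1 = np.arange(0.0, peak_duration + dt / 2, dt)
    frac = 1.0 - np.abs(t1 - half) / half  # triangular in [0, 1]
    frac = np.clip(frac, 0.0, 1.0)
    if shape == "exponential":
        r = 3.0  # fixed convexity of the exponential ramp
        frac = (np.exp(r * frac) - 1.0) / (np.exp(r) - 1.0)
    c1 = peak_max * frac
    conc = np.concatenate([c1[:-1] if k < n_peaks - 1 else c1 for k in range(n_peaks)])
    grid = np.arange(conc.size) * dt
    return Profile(grid, conc, "transient")


def _unit_log_effect(unit_id: str, device_sd: float, seed: int) -> float:
    """Per-unit log-gain effect, reproducible across experiments.

    Keyed on (root seed, crc32 of the unit label) so the same physical unit
    carries the same deviation in every simulated experiment.
    """
    if device_sd == 0:
        return 0.0
    ss = np.random.SeedSequence([int(seed), zlib.crc32(unit_id.encode())])
    return float(np.random.default_rng(ss).normal(0.0, device_sd))


def expected_monitor_response(
    true_concentration: np.ndarray, gain: float, spec: SensorResponseSpec
) -> np.ndarray:
    """Mean monitor reading as a function of true concentration.

    Linear (``gain * c``) below the rollover limit; above it the expectation
    declines with slope ``rollover_slope`` (default: the pre-rollover slope),
    clipped at zero.
    """
    c = np.asarray(true_concentration, float)
    mu = gain * c
    L = spec.rollover_limit
    if L is not None:
        k = spec.rollover_slope if spec.rollover_slope is not None else gain
        mu = np.where(c <= L, mu, np.clip(gain * L - k * (c - L), 0.0, None))
    return mu


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size))


def simulate_experiment(
    profile: Profile,
    conditions: ConditionSet,
    spec: SensorResponseSpec,
    materials: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
    seed: int = 0,
    ref_noise_cv: float = 0.10,
    gravimetric_noise_cv: float = 0.03,
    experiment_id: str = "",
    arm: str = "default",
) -> ExperimentSeries:
    """Simulate one chamber experiment under a condition set.

    The reference instrument reads ``true * (1 + eps)`` with relative SD
    ``ref_noise_cv`` (10%, the APS manufacturer uncertainty); each monitor
    unit reads the expected (possibly rolled-over) response times mean-one
    log-normal noise. The gravimetric value is the time-averaged true
    concentration with 3% relative noise.
    """
    material = materials[conditions.material]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(experiment_id.encode()), 1])
    )
    true = np.asarray(profile.concentration, float)
    n = true.size

    reference = true * _lognormal_noise(rng, ref_noise_cv, n)

    readings = {}
    for unit in conditions.unit_id:
        log_gain = (
            np.log(spec.base_gain * material.monitor_gain)
            + spec.temp_slope * (conditions.temperature - 20.0)
            + spec.rh_slope * (conditions.relative_humidity - 50.0)
            + spec.power_shift * (conditions.power == "battery")
            + spec.pattern_shift * (conditions.pattern == "transient")
            + spec.drift_slope * conditions.session_time
            + _unit_log_effect(unit, spec.device_sd, seed)
        )
        mu = expected_monitor_response(true, float(np.exp(log_gain)), spec)
        readings[unit] = mu * _lognormal_noise(rng, spec.noise_cv, n)
    monitors = pd.DataFrame(readings)

    grav = float(true.mean() * _lognormal_noise(rng, gravimetric_noise_cv, 1)[0])
    return ExperimentSeries(
        time=np.asarray(profile.time, float),
        true_concentration=true,
        reference_reading=reference,
        monitor_readings=monitors,
        conditions=conditions,
        gravimetric_value=grav,
        experiment_id=experiment_id,
        arm=arm,
    )


class DesignPoint(NamedTuple):
    """One planned experiment: which profile to run under which conditions."""

    pattern: str
    conditions: ConditionSet
    arm: str


def build_design(matrix_spec: Mapping) -> list[DesignPoint]:
    """Expand a design specification into planned experiments.

    ``matrix_spec["kind"]`` selects:

    - ``"screening"`` — one-variable-at-a-time: for each entry of ``levels``
      (subset of material / temperature / relative_humidity / power /
      pattern / session_time), one experiment per non-default level times
      ``repeats``, plus ``default_repeats`` shared default-arm experiments
      (battery, 20 degC, 50% RH, transient, session 0, first material).
    - ``"factorial"`` — full factorial over the supplied levels (default:
      material x temperature x relative_humidity, 27 experiments), used for
      verification.

    ``matrix_spec["units"]`` lists the unit labels run in parallel.
    """
    kind = matrix_spec.get("kind", "screening")
    default_levels = (
        DEFAULT_LEVELS
        if kind != "factorial"
        else {k: DEFAULT_LEVELS[k] for k in ("material", "temperature", "relative_humidity")}
    )
    levels = {k: list(v) for k, v in matrix_spec.get("levels", default_levels).items()}
    for var, vals in levels.items():
        if var not in DEFAULT_LEVELS:
            raise ValueError(f"unknown evaluation variable {var!r}")
        if not vals:
            raise ValueError(f"variable {var!r} needs at least one level")
    units = tuple(matrix_spec.get("units", ("u1", "u2", "u3")))
    defaults = dict(matrix_spec.get("defaults", {}))
    base_kwargs = {var: vals[0] for var, vals in DEFAULT_LEVELS.items()}
    base_kwargs.update({var: vals[0] for var, vals in levels.items()})
    base_kwargs.update(defaults)
    base = ConditionSet(unit_id=units, **base_kwargs)

    points: list[DesignPoint] = []
    if kind == "screening":
        repeats = int(matrix_spec.get("repeats", 1))
        default_repeats = int(matrix_spec.get("default_repeats", 3))
        for _ in range(default_repeats):
            points.append(DesignPoint(base.pattern, base, "default"))
        for var, vals in levels.items():
            for lv in vals[1:] if vals[0] == getattr(base, var) else vals:
                cond = replace(base, **{var: lv})
                for _ in range(repeats):
                    points.append(DesignPoint(cond.pattern, cond, var))
    elif kind == "factorial":
        fvars = list(levels) or ["material", "temperature", "relative_humidity"]
        for combo in product(*(levels[v] for v in fvars)):
            cond = replace(base, **dict(zip(fvars, combo)))
            points.append(DesignPoint(cond.pattern, cond, "verification"))
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    return points


def simulate_design(
    design: Iterable[DesignPoint],
    spec: SensorResponseSpec,
    materials: Mapping[str, MaterialProperties] = DEFAULT_MATERIALS,
    seed: int = 0,
    profile_kwargs: Mapping | None = None,
    id_prefix: str = "exp",
) -> list[ExperimentSeries]:
    """Simulate every planned experiment of a design with named substreams.

    Experiment ``i`` gets the substream keyed on (seed, its id), so inserting
    or removing design points does not perturb the other experiments.
    """
    profile_kwargs = dict(profile_kwargs or {})
    stable_kw = profile_kwargs.get("stable", {})
    transient_kw = profile_kwargs.get("transient", {})
    out = []
    for i, point in enumerate(design):
        if point.pattern == "stable":
            prof = profile_stable(**{"levels": [333, 666, 1000, 2500, 5000], **stable_kw})
        else:
            prof = profile_transient(**transient_kw)
        eid = f"{id_prefix}{i:03d}"
        out.append(
            simulate_experiment(
                prof, point.conditions, spec, materials, seed=seed,
                experiment_id=eid, arm=point.arm,
            )
        )
    return out


def resample_series(experiment: ExperimentSeries, window: float = 60.0) -> ExperimentSeries:
    """Block-average all channels of an experiment onto a common grid.

    Mirrors aligning instruments with different native cadences (reference at
    15 s, monitors at 1–30 s) to one shared averaging window before analysis.
    """
    t = experiment.time
    if t.size < 2:
        return experiment
    dt = float(np.median(np.diff(t)))
    k = max(int(round(window / dt)), 1)
    if k == 1:
        return experiment
    m = t.size // k
    if m == 0:
        return experiment

    def avg(v: np.ndarray) -> np.ndarray:
        return np.asarray(v, float)[: m * k].reshape(m, k).mean(axis=1)

    return ExperimentSeries(
        time=t[: m * k].reshape(m, k)[:, 0],
        true_concentration=avg(experiment.true_concentration),
        reference_reading=avg(experiment.reference_reading),
        monitor_readings=experiment.monitor_readings.iloc[: m * k]
        .groupby(np.arange(m * k) // k)
        .mean()
        .set_axis(experiment.monitor_readings.columns, axis=1),
        conditions=experiment.conditions,
        gravimetric_value=experiment.gravimetric_value,
        experiment_id=experiment.experiment_id,
        arm=experiment.arm,
    )


def experiments_to_frame(experiments: Iterable[ExperimentSeries]) -> pd.DataFrame:
    """Stack experiments into one long table (one row per time point x unit)."""
    rows = []
    for exp in experiments:
        c = exp.conditions
        for unit in exp.monitor_readings.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "experiment_id": exp.experiment_id,
                        "arm": exp.arm,
                        "time_s": exp.time,
                        "true_ugm3": exp.true_concentration,
                        "reference": exp.reference_reading,
                        "monitor": exp.monitor_readings[unit].to_numpy(),
                        "unit_id": unit,
                        "material": c.material,
                        "temperature": c.temperature,
                        "relative_humidity": c.relative_humidity,
                        "power": c.power,
                        "pattern": c.pattern,
                        "session_time": c.session_time,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_experiments(experiments: Sequence[ExperimentSeries], outdir) -> pd.DataFrame:
    """Write one CSV per experiment plus a manifest of condition sets."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for exp in experiments:
        path = outdir / f"{exp.experiment_id}.csv"
        exp.to_frame().to_csv(path, index=False)
        c = exp.conditions
        manifest.append(
            {
                "experiment_id": exp.experiment_id,
                "arm": exp.arm,
                "file": path.name,
                "material": c.material,
                "temperature": c.temperature,
                "relative_humidity": c.relative_humidity,
                "power": c.power,
                "pattern": c.pattern,
                "session_time": c.session_time,
                "unit_ids": ";".join(c.unit_id),
                "location_tag": c.location_tag,
                "gravimetric_ugm3": exp.gravimetric_value,
            }
        )
    mdf = pd.DataFrame(manifest)
    mdf.to_csv(outdir / "manifest.csv", index=False)
    return mdf
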