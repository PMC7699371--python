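"""End-to-end evaluation pipeline: simulate -> screen -> fit -> verify.

A run is driven by a :class:`RunConfig` (loadable from YAML) and a root seed.
Every stage writes plain CSV/JSON under the run directory, so any stage can
be rerun from its persisted inputs or replaced by external data of the same
schema, and a summary JSON collects the cutoff table, the variable-selection
table, the bin-wise uncertainty table, the fold-improvement table and
content hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chamber
from .chamber import (
    MaterialProperties,
    SensorResponseSpec,
    build_design,
    simulate_design,
    experiments_to_frame,
    resample_series,
    write_experiments,
)
from .screening import RolloverScreener, TransformChoice, select_normalization
from .correction import run_variable_selection, ModelSpec, fit_model
from .verification import compare_corrections, DEFAULT_BIN_EDGES

__all__ = ["RunConfig", "MonitorConfig", "run_pipeline", "check_responsiveness"]

logger = logging.getLogger("pmevalkit")


@dataclass(frozen=True)
class MonitorConfig:
    """One monitor type: its generative response spec and its unit labels."""

    name: str
    spec: SensorResponseSpec = field(default_factory=SensorResponseSpec)
    units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.units:
            object.__setattr__(
                self, "units", tuple(f"{self.name}_u{i}" for i in (1, 2, 3))
            )


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an evaluation run.

    ``targets`` carries the deployment requirements: the informative
    concentration range (0–5000 ug/m^3 respirable PM), the accuracy target
    (<= 50% relative uncertainty) and the responsiveness target (60 s).
    """

    seed: int = 0
    monitors: tuple[MonitorConfig, ...] = ()
    materials: Mapping[str, MaterialProperties] = field(
        default_factory=lambda: dict(chamber.DEFAULT_MATERIALS)
    )
    screening_levels: Mapping[str, Sequence] = field(
        default_factory=lambda: {k: list(v) for k, v in chamber.DEFAULT_LEVELS.items()}
    )
    default_repeats: int = 3
    transient_profile: Mapping = field(
        default_factory=lambda: {"peak_max": 5000.0, "peak_duration": 1800.0, "n_peaks": 3, "dt": 15.0}
    )
    stable_levels: Sequence[float] = (333.0, 666.0, 1000.0, 2500.0, 5000.0)
    align_window: float = 60.0  # s; common averaging grid across instruments
    span: float = 0.5
    loess_degree: int = 2
    decline_tol: float = 0.05
    flag_fraction: float = 0.10
    percentile: float = 10.0
    transform: str = "log10"  # or "auto" to run normalization selection
    alpha: float = 0.05
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
    ref_uncertainty: float = 0.10
    extra_sd: float = 0.0
    n_min: int = 30
    min_reference: float = 1.0  # ug/m^3; relative errors undefined near zero
    target_uncertainty: float = 50.0  # %
    concentration_range: tuple[float, float] = (0.0, 5000.0)
    target_responsiveness: float = 60.0  # s

    def __post_init__(self) -> None:
        if not self.monitors:
            raise ValueError("config must declare at least one monitor")
        if self.target_uncertainty <= 0:
            raise ValueError("target_uncertainty must be positive")
        lo, hi = self.concentration_range
        if not (hi > lo >= 0):
            raise ValueError("concentration range upper must exceed lower >= 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        monitors = []
        for m in raw.pop("monitors", []):
            m = dict(m)
            spec = SensorResponseSpec(**m.pop("spec", {}))
            monitors.append(MonitorConfig(name=m.pop("name"), spec=spec, units=tuple(m.pop("units", ()))))
        materials = {
            k: MaterialProperties(name=k, **v) for k, v in raw.pop("materials", {}).items()
        } or dict(chamber.DEFAULT_MATERIALS)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(monitors=tuple(monitors), materials=materials, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def check_responsiveness(
    time: Sequence[float], series: Sequence[float], span_fraction: float = 0.8
) -> tuple[float | None, str]:
    """Time to span from the series minimum to 80% of its maximum.

    Returns ``(seconds, status)`` where status is "ok" or "not_evaluable"
    (flat series, or the 80% level is never reached). The clock starts at the
    last sample at/below the minimum level before the first crossing.
    """
    t = np.asarray(time, float)
    v = np.asarray(series, float)
    if v.size < 2 or np.ptp(v) == 0:
        return None, "not_evaluable"
    lo, hi = v.min(), v.max()
    threshold = lo + span_fraction * (hi - lo)
    above = np.nonzero(v >= threshold)[0]
    if above.size == 0:
        return None, "not_evaluable"
    cross = above[0]
    at_min = np.nonzero(v[:cross] <= lo + 1e-12 * max(abs(hi), 1.0))[0]
    start = at_min[-1] if at_min.size else 0
    return float(t[cross] - t[start]), "ok"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _monitor_seed(root_seed: int, name: str) -> int:
    import zlib

    return int(np.random.SeedSequence([root_seed, zlib.crc32(name.encode())]).generate_state(1)[0] % (2**31))


def _screen_monitor(experiments, mon: MonitorConfig, cfg: RunConfig):
    """Per-unit rollover screening on aligned experiments."""
    reports = {}
    for unit in mon.units:
        pairs = [
            (exp.reference_reading, exp.monitor_readings[unit].to_numpy())
            for exp in experiments
        ]
        scr = RolloverScreener(
            span=cfg.span,
            degree=cfg.loess_degree,
            decline_tol=cfg.decline_tol,
            flag_fraction=cfg.flag_fraction,
            percentile=cfg.percentile,
        )
        scr.fit(pairs, unit_id=unit)
        reports[unit] = scr.report_
    return reports


def _truncate_frame(frame: pd.DataFrame, cutoffs: Mapping[str, float | None]) -> tuple[pd.DataFrame, int]:
    keep = np.ones(len(frame), bool)
    for unit, cutoff in cutoffs.items():
        if cutoff is not None:
            keep &= ~((frame["unit_id"] == unit) & (frame["monitor"] > cutoff)).to_numpy()
    return frame[keep].reset_index(drop=True), int((~keep).sum())


def _variable_subsets(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Data subset per evaluation variable: its arm plus the shared default arm."""
    arm_of = {
        "drift": "session_time",
        "temperature": "temperature",
        "humidity": "relative_humidity",
        "pattern": "pattern",
        "power": "power",
        "material": "material",
    }
    subsets: dict[str, pd.DataFrame] = {}
    default = frame[frame["arm"] == "default"]
    if default["unit_id"].nunique() >= 2:
        subsets["unit"] = default
    for variable, arm in arm_of.items():
        sub = frame[frame["arm"].isin([arm, "default"])]
        if len(sub) and sub[_varcol(variable)].nunique() >= 2:
            subsets[variable] = sub
    return subsets


def _varcol(variable: str) -> str:
    return {
        "drift": "session_time",
        "temperature": "temperature",
        "humidity": "relative_humidity",
        "pattern": "pattern",
        "power": "power",
        "material": "material",
        "unit": "unit_id",
    }[variable]


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Run simulate -> screen -> fit -> verify; return the summary dict.

    Deterministic given ``seed`` (defaults to ``config.seed``). The run
    directory receives per-stage subdirectories of CSV/JSON artifacts and a
    ``summary.json`` with content hashes.
    """
    seed = config.seed if seed is None else int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "monitors": {}, "stage_seconds": {}}

    screening_design_spec = {
        "kind": "screening",
        "levels": {k: list(v) for k, v in config.screening_levels.items()},
        "default_repeats": config.default_repeats,
    }
    factorial_levels = {
        "material": list(config.screening_levels.get("material", ["ard"])),
        "temperature": list(config.screening_levels.get("temperature", [20.0])),
        "relative_humidity": list(config.screening_levels.get("relative_humidity", [50.0])),
    }
    profile_kwargs = {
        "transient": dict(config.transient_profile),
        "stable": {"levels": list(config.stable_levels)},
    }

    for mon in config.monitors:
        t0 = _time.time()
        mseed = _monitor_seed(seed, mon.name)
        mdir = outdir / mon.name
        logger.info("simulating %s (seed %d)", mon.name, mseed)

        screen_design = build_design({**screening_design_spec, "units": mon.units})
        verify_design = build_design(
            {"kind": "factorial", "levels": factorial_levels, "units": mon.units}
        )
        screen_exps = simulate_design(
            screen_design, mon.spec, config.materials, seed=mseed,
            profile_kwargs=profile_kwargs, id_prefix=f"{mon.name}_s",
        )
        verify_exps = simulate_design(
            verify_design, mon.spec, config.materials, seed=mseed + 1,
            profile_kwargs=profile_kwargs, id_prefix=f"{mon.name}_v",
        )
        write_experiments(screen_exps, mdir / "simulate" / "screening")
        write_experiments(verify_exps, mdir / "simulate" / "verification")
        summary["stage_seconds"][f"{mon.name}.simulate"] = round(_time.time() - t0, 2)

        # --- screen -----------------------------------------------------
        t0 = _time.time()
        aligned = [resample_series(e, config.align_window) for e in screen_exps]
        reports = _screen_monitor(aligned, mon, config)
        cutoffs = {u: r.cutoff for u, r in reports.items()}
        (mdir / "screen").mkdir(parents=True, exist_ok=True)
        with open(mdir / "screen" / "cutoffs.json", "w") as fh:
            json.dump(
                {
                    u: {
                        "cutoff": r.cutoff,
                        "n_experiments": r.n_experiments,
                        "n_flagged": r.n_flagged,
                        "per_experiment_limits": list(r.per_experiment_limits),
                    }
                    for u, r in reports.items()
                },
                fh,
                indent=2,
            )
        frame = experiments_to_frame(aligned)
        frame, n_removed = _truncate_frame(frame, cutoffs)
        summary["stage_seconds"][f"{mon.name}.screen"] = round(_time.time() - t0, 2)

        # --- fit ---------------------------------------------------------
        t0 = _time.time()
        positive = frame[(frame["monitor"] > 0) & (frame["reference"] > 0)]
        if config.transform == "auto":
            sample = positive["monitor"].to_numpy()
            if sample.size > 5000:  # selection cost is O(folds * n log n)
                sample = np.sort(sample)[:: sample.size // 5000]
            transform = select_normalization(sample, seed=seed)
        else:
            transform = TransformChoice(config.transform)
        subsets = _variable_subsets(positive)
        results, final_spec = run_variable_selection(subsets, transform, alpha=config.alpha)
        final_model = fit_model(positive, final_spec)
        reduced_model = fit_model(positive, ModelSpec(transform=transform))
        (mdir / "fit").mkdir(parents=True, exist_ok=True)
        res_df = pd.DataFrame(
            {
                "variable": [r.variable for r in results],
                "anova_p": [r.anova_p for r in results],
                "delta_aic": [r.delta_aic for r in results],
                "mae_without": [r.mae_without for r in results],
                "mae_with": [r.mae_with for r in results],
                "mae_fold": [r.mae_fold for r in results],
                "passed": [r.passed for r in results],
                "note": [r.note for r in results],
            }
        )
        res_df.to_csv(mdir / "fit" / "variable_tests.csv", index=False)
        with open(mdir / "fit" / "final_model.json", "w") as fh:
            json.dump(
                {
                    "fixed_slope_terms": sorted(final_model.spec_.fixed_slope_terms),
                    "random_slope_terms": sorted(final_model.spec_.random_slope_terms),
                    "transform": transform.name,
                    "coefficients": final_model.coefficients_,
                    "variance_components": final_model.variance_components_,
                    "random_slopes": final_model.random_slopes_,
                    "loglike": final_model.loglike_,
                    "aic": final_model.aic_,
                    "n_obs": final_model.n_obs_,
                    "fit_log": final_model.fit_log_,
                },
                fh,
                indent=2,
            )
        summary["stage_seconds"][f"{mon.name}.fit"] = round(_time.time() - t0, 2)

        # --- verify ------------------------------------------------------
        # verification runs at native cadence: the quadrature removal of the
        # reference's stated per-reading uncertainty is only consistent with
        # unaveraged pairs
        t0 = _time.time()
        vframe = experiments_to_frame(verify_exps)
        vframe, _ = _truncate_frame(vframe, cutoffs)
        vframe = vframe[
            (vframe["reference"] >= config.min_reference) & (vframe["monitor"] > 0)
        ].reset_index(drop=True)
        full_pred = final_model.predict(vframe)
        reduced_pred = reduced_model.predict(vframe)
        ref = vframe["reference"].to_numpy()
        full_rep, reduced_rep, folds = compare_corrections(
            full_pred,
            reduced_pred,
            ref,
            monitor=mon.name,
            edges=config.bin_edges,
            ref_uncertainty=config.ref_uncertainty,
            extra_sd=config.extra_sd,
            n_min=config.n_min,
            target=config.target_uncertainty,
        )
        (mdir / "verify").mkdir(parents=True, exist_ok=True)
        full_rep.to_frame().to_csv(mdir / "verify" / "uncertainty_full.csv", index=False)
        reduced_rep.to_frame().to_csv(mdir / "verify" / "uncertainty_reduced.csv", index=False)
        pd.DataFrame(
            {
                "upper_ugm3": [k[1] for k in folds.per_bin],
                "fold": list(folds.per_bin.values()),
            }
        ).to_csv(mdir / "verify" / "folds.csv", index=False)

        # responsiveness on a clean transient rising edge
        first = verify_exps[0]
        unit0 = first.monitor_readings.columns[0]
        resp, resp_status = check_responsiveness(
            first.time, first.monitor_readings[unit0].to_numpy()
        )
        summary["stage_seconds"][f"{mon.name}.verify"] = round(_time.time() - t0, 2)

        summary["monitors"][mon.name] = {
            "cutoffs": cutoffs,
            "rows_removed_by_truncation": n_removed,
            "transform": transform.name,
            "passed_variables": sorted(
                final_model.spec_.fixed_slope_terms | final_model.spec_.random_slope_terms
            ),
            "variable_tests": res_df.drop(columns="note").to_dict("records"),
            "bin_uncertainty_pct": {
                str(int(b.upper)): (None if not np.isfinite(b.uncertainty) else round(b.uncertainty, 1))
                for b in full_rep.bins
            },
            "meets_target_up_to_ugm3": _meets_up_to(full_rep, config.target_uncertainty),
            "average_fold_improvement": None if not np.isfinite(folds.average) else round(folds.average, 3),
            "responsiveness_s": resp,
            "responsiveness_status": resp_status,
            "meets_responsiveness": bool(
                resp_status == "ok" and resp is not None and resp <= config.target_responsiveness
            ),
        }

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "summary.json")
    summary["artifact_hashes"] = {str(p.relative_to(outdir)): _sha256(p) for p in files}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _meets_up_to(report, target: float) -> float:
    """Highest bin upper bound up to which all bins meet the accuracy target."""
    upper = 0.0
    for b in report.bins:
        if b.status == "ok" and b.uncertainty <= target:
            upper = b.upper
        else:
            break
    return upper
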