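"""Synthetic chamber generator: profiles, sensor model, designs, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pmevalkit as pk
from pmevalkit.chamber import (
    DEFAULT_LEVELS,
    Profile,
    build_design,
    expected_monitor_response,
    experiments_to_frame,
    profile_stable,
    profile_transient,
    simulate_design,
    simulate_experiment,
)


class TestProfiles:
    def test_plateau_means_equal_levels(self):
        levels = [333.0, 666.0, 1000.0, 2500.0, 5000.0]
        prof = profile_stable(levels, plateau_duration=900)
        for lv in levels:
            plateau = prof.concentration[prof.concentration == lv]
            assert plateau.size >= 60  # >= 15 min at 15 s cadence
            assert plateau.mean() == lv

    def test_step_profile_time_weighted_mean(self):
        # two equal plateaus, no ramp: the mean is the midpoint exactly
        prof = profile_stable([100.0, 200.0], plateau_duration=900, ramp_fraction=0.0)
        assert set(np.unique(prof.concentration)) == {100.0, 200.0}
        assert prof.concentration.mean() == pytest.approx(150.0)

    def test_single_level_is_constant(self):
        prof = profile_stable([1000.0])
        assert np.all(prof.concentration == 1000.0)

    @pytest.mark.parametrize("bad", [[], [0.0], [-5.0, 100.0]])
    def test_stable_rejects_bad_levels(self, bad):
        with pytest.raises(ValueError):
            profile_stable(bad)

    def test_transient_peaks(self):
        prof = profile_transient(5000.0, 1800.0, n_peaks=3)
        assert prof.concentration.max() == 5000.0
        assert int((prof.concentration == 5000.0).sum()) == 3
        # triangular excursions: time-average is half the peak
        mean = np.trapezoid(prof.concentration, prof.time) / (prof.time[-1] - prof.time[0])
        assert mean == pytest.approx(2500.0)

    def test_transient_degenerate_and_errors(self):
        assert np.all(profile_transient(0.0, 1800.0, n_peaks=1).concentration == 0.0)
        with pytest.raises(ValueError):
            profile_transient(5000.0, -10.0)
        with pytest.raises(ValueError):
            profile_transient(5000.0, 1800.0, n_peaks=0)

    def test_exponential_shape_keeps_max(self):
        prof = profile_transient(5000.0, 1800.0, n_peaks=1, shape="exponential")
        assert prof.concentration.max() == 5000.0
        assert prof.concentration.min() == 0.0


class TestSensorModel:
    def test_identity_sensor_reproduces_truth(self):
        spec = pk.SensorResponseSpec(
            temp_slope=0, rh_slope=0, power_shift=0, pattern_shift=0,
            device_sd=0, drift_slope=0, noise_cv=0,
        )
        prof = profile_transient(5000.0, 1800.0, n_peaks=1)
        exp = simulate_experiment(prof, pk.ConditionSet(), spec, seed=0, ref_noise_cv=0.0)
        np.testing.assert_allclose(
            exp.monitor_readings["u1"].to_numpy(), exp.true_concentration, rtol=1e-12
        )
        np.testing.assert_allclose(exp.reference_reading, exp.true_concentration, rtol=1e-12)

    def test_noise_cv_recovered(self):
        spec = pk.SensorResponseSpec(
            temp_slope=0, rh_slope=0, power_shift=0, pattern_shift=0,
            device_sd=0, drift_slope=0, noise_cv=0.05,
        )
        n = 10_000
        prof = Profile(np.arange(n) * 15.0, np.full(n, 1000.0), "stable")
        exp = simulate_experiment(prof, pk.ConditionSet(), spec, seed=1, ref_noise_cv=0.0)
        readings = exp.monitor_readings["u1"].to_numpy()
        cv = readings.std(ddof=1) / readings.mean()
        assert cv == pytest.approx(0.05, abs=0.002)

    def test_reference_relative_sd_recovered(self):
        n = 10_000
        prof = Profile(np.arange(n) * 15.0, np.full(n, 1000.0), "stable")
        exp = simulate_experiment(prof, pk.ConditionSet(), pk.SensorResponseSpec(), seed=2)
        rel = exp.reference_reading / exp.true_concentration
        assert rel.std(ddof=1) == pytest.approx(0.10, abs=0.004)
        assert rel.mean() == pytest.approx(1.0, abs=0.004)

    def test_rollover_maps_one_reference_to_two_monitor_branches(self):
        spec = pk.SensorResponseSpec(
            temp_slope=0, rh_slope=0, power_shift=0, pattern_shift=0,
            device_sd=0, drift_slope=0, noise_cv=0, rollover_limit=2500.0,
        )
        prof = profile_transient(5000.0, 1800.0, n_peaks=1)
        exp = simulate_experiment(prof, pk.ConditionSet(), spec, seed=3, ref_noise_cv=0.0)
        mon = exp.monitor_readings["u1"].to_numpy()
        true = exp.true_concentration
        at = lambda c: mon[np.argmin(np.abs(true - c))]
        # the descending branch folds back: reading at 4000 equals reading at 1000
        assert at(4000.0) == pytest.approx(at(1000.0), rel=1e-9)
        assert at(4000.0) < at(2500.0)

    def test_expected_response_monotone_below_limit(self):
        spec = pk.SensorResponseSpec(rollover_limit=2500.0)
        c = np.linspace(1.0, 2500.0, 500)
        mu = expected_monitor_response(c, gain=0.9, spec=spec)
        assert np.all(np.diff(mu) > 0)

    def test_gravimetric_tracks_time_average(self):
        prof = profile_stable([1000.0], plateau_duration=9000)
        exp = simulate_experiment(
            prof, pk.ConditionSet(), pk.SensorResponseSpec(), seed=4,
            gravimetric_noise_cv=0.0,
        )
        assert exp.gravimetric_value == pytest.approx(1000.0)

    def test_seed_determinism(self):
        design = build_design({"kind": "screening", "levels": {"temperature": [20.0, 25.0]}})
        a = experiments_to_frame(simulate_design(design, pk.SensorResponseSpec(), seed=7))
        b = experiments_to_frame(simulate_design(design, pk.SensorResponseSpec(), seed=7))
        c = experiments_to_frame(simulate_design(design, pk.SensorResponseSpec(), seed=8))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["monitor"], c["monitor"])

    def test_unit_effect_consistent_across_experiments(self):
        # the same physical unit must carry the same gain deviation everywhere
        spec = pk.SensorResponseSpec(device_sd=0.5, noise_cv=0.0)
        prof = profile_stable([1000.0])
        cond = pk.ConditionSet(unit_id=("a", "b"))
        e1 = simulate_experiment(prof, cond, spec, seed=5, experiment_id="e1", ref_noise_cv=0.0)
        e2 = simulate_experiment(prof, cond, spec, seed=5, experiment_id="e2", ref_noise_cv=0.0)
        np.testing.assert_allclose(e1.monitor_readings["a"], e2.monitor_readings["a"])
        assert not np.allclose(e1.monitor_readings["a"], e1.monitor_readings["b"])


class TestDesigns:
    def test_factorial_default_is_27_experiments(self):
        design = build_design({"kind": "factorial"})
        assert len(design) == 27
        combos = {(p.conditions.material, p.conditions.temperature,
                   p.conditions.relative_humidity) for p in design}
        assert len(combos) == 27  # each possible combination exactly once

    def test_single_variable_single_level(self):
        design = build_design(
            {"kind": "screening", "levels": {"temperature": [20.0]}, "default_repeats": 1}
        )
        assert len(design) == 1

    def test_screening_count_matches_enumeration(self):
        # brute-force enumeration: default repeats + one run per non-default level
        design = build_design({"kind": "screening", "default_repeats": 3})
        expected = 3 + sum(len(v) - 1 for v in DEFAULT_LEVELS.values())
        assert len(design) == expected
        assert sum(p.arm == "default" for p in design) == 3

    def test_screening_varies_one_variable_at_a_time(self):
        design = build_design({"kind": "screening", "default_repeats": 1})
        base = design[0].conditions
        for point in design[1:]:
            diffs = [
                f for f in ("material", "temperature", "relative_humidity",
                            "power", "pattern", "session_time")
                if getattr(point.conditions, f) != getattr(base, f)
            ]
            assert len(diffs) == 1 and diffs[0] == {
                "relative_humidity": "relative_humidity"
            }.get(point.arm, point.arm)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            build_design({"kind": "screening", "levels": {"altitude": [0, 1]}})
        with pytest.raises(ValueError):
            build_design({"kind": "screening", "levels": {"temperature": []}})


@given(st.floats(min_value=10.0, max_value=5000.0))
def test_expected_response_scales_linearly_below_limit(c):
    spec = pk.SensorResponseSpec(rollover_limit=None)
    assert expected_monitor_response(np.array([c]), 1.3, spec)[0] == pytest.approx(1.3 * c)
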