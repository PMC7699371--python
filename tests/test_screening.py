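"""Screening: loess smoothing, rollover detection, cutoff pooling, transforms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmevalkit.screening import (
    FittedCurve,
    RolloverScreener,
    TransformChoice,
    detect_negative_correlation,
    loess,
    pearson_normality_stat,
    pool_cutoff,
    select_normalization,
    smooth_experiment,
    truncate,
)


class TestLoess:
    def test_matches_r_loess_on_smooth_curve(self):
        # expected values computed with R: loess(y ~ x, span=0.5, degree=2,
        # surface="direct") on y = sin(x) + 0.1 cos(7x), x = seq(0,10,len=120)
        x = np.linspace(0, 10, 120)
        y = np.sin(x) + 0.1 * np.cos(7 * x)
        grid = np.linspace(0.5, 9.5, 7)
        expected = [0.5129370196, 0.8352145167, -0.3441911320, -0.9200751026,
                    0.1959717897, 0.9314009248, -0.0047918378]
        np.testing.assert_allclose(loess(x, y, grid, span=0.5, degree=2), expected, atol=0.02)

    def test_interpolates_line_exactly(self):
        x = np.linspace(0, 100, 80)
        y = 3.0 * x + 7.0
        grid = np.linspace(5, 95, 11)
        np.testing.assert_allclose(loess(x, y, grid, span=0.5, degree=1), 3 * grid + 7, rtol=1e-9)

    def test_rejects_bad_span(self):
        with pytest.raises(ValueError):
            loess(np.arange(10.0), np.arange(10.0), span=0.0)


class TestSmoothExperiment:
    def test_identity_response_within_one_percent(self):
        ref = np.linspace(10, 5000, 300)
        curve = smooth_experiment(ref, ref)
        np.testing.assert_allclose(curve.fitted, curve.reference, rtol=0.01)

    def test_noiseless_rollover_apex_located(self):
        ref = np.linspace(0, 5000, 400)
        mon = np.where(ref <= 2500, ref, 2 * 2500 - ref)
        curve = smooth_experiment(ref, mon, span=0.3)
        apex_ref = curve.reference[np.argmax(curve.fitted)]
        assert abs(apex_ref - 2500) / 2500 < 0.05

    def test_pure_noise_fits_flat(self):
        rng = np.random.default_rng(6)
        ref = np.linspace(100, 5000, 500)
        mon = 1000.0 + rng.normal(0, 30, 500)
        curve = smooth_experiment(ref, mon)
        drift = np.ptp(curve.fitted)
        assert drift < 60  # no systematic trend across the full range

    def test_too_few_points_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert smooth_experiment(np.arange(5.0), np.arange(5.0)) is None


class TestDetectNegativeCorrelation:
    def test_strictly_increasing_not_flagged(self):
        grid = np.linspace(0, 5000, 100)
        curve = FittedCurve(grid, 0.9 * grid, observed_max=4600.0)
        flag, limit = detect_negative_correlation(curve)
        assert not flag
        assert limit == 4600.0

    def test_constructed_rollover_limit_at_apex(self):
        grid = np.linspace(0, 5000, 500)
        fitted = np.where(grid <= 3000, grid, 3000 - 0.5 * (grid - 3000))  # 20%+ decline
        curve = FittedCurve(grid, fitted, observed_max=3100.0)
        flag, limit = detect_negative_correlation(curve)
        assert flag
        assert limit == pytest.approx(3000.0, rel=0.01)

    def test_small_decline_within_tolerance_not_flagged(self):
        grid = np.linspace(0, 1000, 200)
        fitted = np.where(grid <= 900, grid, 900 - 0.09 * (grid - 900))  # 1% dip
        curve = FittedCurve(grid, fitted, observed_max=905.0)
        flag, limit = detect_negative_correlation(curve, decline_tol=0.05)
        assert not flag
        assert limit == 905.0

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_uniform_rescaling(self, scale):
        grid = np.linspace(0, 5000, 300)
        fitted = np.where(grid <= 2000, grid, 2000 - 0.8 * (grid - 2000))
        c1 = FittedCurve(grid, fitted, observed_max=2050.0)
        c2 = FittedCurve(grid * scale, fitted * scale, observed_max=2050.0 * scale)
        f1, l1 = detect_negative_correlation(c1)
        f2, l2 = detect_negative_correlation(c2)
        assert f1 == f2
        assert l2 == pytest.approx(l1 * scale, rel=1e-9)


class TestPoolCutoff:
    def test_uniform_limits(self):
        rep = pool_cutoff([1000.0] * 10, [True] * 10)
        assert rep.cutoff == 1000.0

    def test_published_unit_limits_fixture(self):
        # four per-unit limits reported for a saturating optical sensor,
        # used as a percentile fixture; type-7 p10 computed by hand:
        # sorted [2263, 2772, 3354, 3562], h = 0.3 -> 2263 + 0.3 * 509
        limits = [3562.0, 2772.0, 2263.0, 3354.0]
        rep = pool_cutoff(limits, [True] * 4)
        assert rep.cutoff == pytest.approx(2263 + 0.3 * (2772 - 2263))
        assert rep.cutoff == pytest.approx(np.percentile(limits, 10))

    def test_below_flag_fraction_yields_none(self):
        rep = pool_cutoff([1000.0] * 20, [True] + [False] * 19)  # 5% < 10%
        assert rep.cutoff is None
        assert rep.n_flagged == 1

    @given(st.lists(st.floats(min_value=10, max_value=5000), min_size=2, max_size=30))
    def test_cutoff_bounded_by_limits(self, limits):
        rep = pool_cutoff(limits, [True] * len(limits))
        assert min(limits) <= rep.cutoff <= max(limits)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_cutoff([], [])


class TestTruncate:
    def test_infinite_cutoff_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        res = truncate(v, np.inf)
        np.testing.assert_array_equal(res.series, v)
        assert res.removed_count == 0

    def test_none_cutoff_identity(self):
        v = np.array([5.0, 6.0])
        res = truncate(v, None)
        np.testing.assert_array_equal(res.series, v)

    def test_counts_match_brute_force_filter(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 100, 100)
        cutoff = np.sort(v)[69]  # exactly 30 strictly above
        res = truncate(v, cutoff)
        brute = v[v <= cutoff]
        np.testing.assert_array_equal(res.series, brute)
        assert res.removed_count == 30
        assert res.series.size == 70

    def test_all_above_warns_empty(self):
        with pytest.warns(UserWarning):
            res = truncate(np.array([10.0, 20.0]), 5.0)
        assert res.series.size == 0
        assert res.removed_count == 2

    @given(st.lists(st.floats(min_value=0, max_value=1000), min_size=1, max_size=50),
           st.floats(min_value=0, max_value=1000))
    def test_exact_set_equality_with_filter_oracle(self, values, cutoff):
        v = np.asarray(values)
        res = truncate(v, cutoff)
        np.testing.assert_array_equal(res.series, v[v <= cutoff])


class TestNormalization:
    def test_lognormal_sample_picks_log_family(self):
        rng = np.random.default_rng(8)
        v = np.exp(rng.normal(5.0, 1.0, 10_000))
        choice = select_normalization(v, seed=0)
        # box-cox / yeo-johnson with lambda ~ 0 are affine equivalents of log10
        assert choice.name in ("log10", "box-cox", "yeo-johnson")
        if choice.name in ("box-cox", "yeo-johnson"):
            assert abs(choice.parameters["lambda"]) < 0.15
        # and log10 must beat the non-log analytic candidates outright
        z = np.log10(v)
        assert pearson_normality_stat(z) < pearson_normality_stat(v)
        assert pearson_normality_stat(z) < pearson_normality_stat(np.sqrt(v))

    def test_normal_sample_keeps_identity_family(self):
        rng = np.random.default_rng(9)
        v = rng.normal(100.0, 5.0, 10_000)
        choice = select_normalization(v, seed=0)
        assert choice.name != "log10"
        assert pearson_normality_stat(v) < pearson_normality_stat(np.log10(v))

    def test_transform_inverse_roundtrip(self):
        rng = np.random.default_rng(10)
        v = np.exp(rng.normal(3, 0.8, 500))
        for name in ("identity", "log10", "sqrt"):
            tc = TransformChoice(name)
            np.testing.assert_allclose(tc.inverse(tc.transform(v)), v, rtol=1e-10)
        choice = select_normalization(v, candidates=("box-cox",), seed=0)
        np.testing.assert_allclose(choice.inverse(choice.transform(v)), v, rtol=1e-8)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            select_normalization(np.full(100, 3.0))
        with pytest.raises(ValueError):
            select_normalization(np.arange(10.0))  # n < 30


class TestRolloverScreener:
    def test_recovers_known_limit_in_monitor_units(self):
        rng = np.random.default_rng(11)
        gain, limit = 0.9, 2500.0
        pairs = []
        for _ in range(8):
            true = np.concatenate([np.linspace(0, 5000, 120), np.linspace(5000, 0, 120)])
            ref = true * (1 + rng.normal(0, 0.05, true.size))
            mon = np.where(true <= limit, gain * true, gain * (2 * limit - true).clip(0))
            mon = mon * (1 + rng.normal(0, 0.03, true.size))
            pairs.append((ref, mon))
        scr = RolloverScreener().fit(pairs, unit_id="u1")
        assert scr.flags_.all()
        assert abs(scr.cutoff_ - gain * limit) / (gain * limit) < 0.10

    def test_monotone_data_yields_no_cutoff(self):
        rng = np.random.default_rng(12)
        pairs = []
        for _ in range(6):
            ref = np.linspace(10, 5000, 200)
            pairs.append((ref, 1.1 * ref * (1 + rng.normal(0, 0.05, 200))))
        scr = RolloverScreener().fit(pairs)
        assert scr.cutoff_ is None
        res = scr.transform(np.array([1.0, 6000.0]))
        assert res.removed_count == 0
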