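import math

import numpy as np
import pytest
from scipy import stats as sstats

from nitrosip.errors import ValidationError
from nitrosip import kinetics as kin

from conftest import make_series


def ols_oracle(t, y):
    """Normal-equations slope/se/t/p, independent of the implementation."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    sxx = np.sum((t - t.mean()) ** 2)
    slope = np.sum((t - t.mean()) * (y - y.mean())) / sxx
    resid = y - (y.mean() + slope * (t - t.mean()))
    se = math.sqrt(np.sum(resid ** 2) / (n - 2) / sxx)
    tstat = slope / se
    p = sstats.t.sf(tstat, n - 2)
    return slope * 24, se * 24, tstat, p


class TestFitSlope:
    def test_perfect_line(self, perfect_series):
        fit = kin.fit_slope(perfect_series)
        assert fit.slope == pytest.approx(4.0)
        assert fit.p_one_sided < 1e-6

    def test_constant_series_null(self, flat_series):
        fit = kin.fit_slope(flat_series)
        assert fit.slope == 0.0
        assert fit.p_one_sided == 0.5

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 9)
            t = np.sort(rng.uniform(0, 24, size=n))
            while np.any(np.diff(t) <= 0):
                t = np.sort(rng.uniform(0, 24, size=n))
            y = rng.normal(0.1 * t, 0.3)
            fit = kin.fit_slope(make_series(t, y))
            slope, se, tstat, p = ols_oracle(t, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.se == pytest.approx(se, rel=1e-10)
            assert fit.t_statistic == pytest.approx(tstat, rel=1e-9)
            assert fit.p_one_sided == pytest.approx(p, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            make_series([0, 6], [0, 1])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            make_series([0, 6, 6, 12], [0, 1, 2, 3])

    def test_scale_covariance(self):
        rng = np.random.default_rng(3)
        t = np.array([0, 3, 6, 12, 24.0])
        y = rng.normal(0.05 * t, 0.1)
        f1 = kin.fit_slope(make_series(t, y))
        f10 = kin.fit_slope(make_series(t, 10 * y))
        assert f10.slope == pytest.approx(10 * f1.slope, rel=1e-12)
        assert f10.t_statistic == pytest.approx(f1.t_statistic, rel=1e-12)


class TestLabelingFraction:
    def test_no_ambient(self):
        assert kin.labeling_fraction(0, 100, 0.99) == pytest.approx(0.99)

    def test_equal_pools(self):
        assert kin.labeling_fraction(100, 100, 0.98) == pytest.approx(0.49)

    def test_oligotrophic_design(self):
        # low ambient, large tracer addition: >90% labeling
        f = kin.labeling_fraction(11, 500, 0.98)
        assert f == pytest.approx(500 * 0.98 / 511)
        assert f > 0.9

    def test_invalid_added(self):
        with pytest.raises(ValidationError):
            kin.labeling_fraction(10, 0, 0.99)


class TestCorrectRate:
    @pytest.mark.parametrize("slope,f,expected",
                             [(1.0, 1.0, 1.0), (2.0, 0.5, 4.0), (0.0, 0.3, 0.0)])
    def test_values(self, slope, f, expected):
        assert kin.correct_rate(slope, f) == pytest.approx(expected)

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            kin.correct_rate(1.0, 0.0)
        with pytest.raises(ValidationError):
            kin.correct_rate(1.0, 1.5)


class TestRateLod:
    TIMES = [0, 3, 6, 12, 24.0]

    def test_closed_form(self):
        # t quantile at 3 df, alpha 0.05 one-sided: 2.3533634348
        sxx = sum((t - 9.0) ** 2 for t in self.TIMES)  # 360
        expected = 2.3533634348 * 0.05 / math.sqrt(sxx) * 24.0
        assert kin.rate_lod(0.05, self.TIMES, f=1.0) == pytest.approx(
            expected, rel=1e-9)

    def test_linearity_in_noise(self):
        one = kin.rate_lod(0.05, self.TIMES)
        two = kin.rate_lod(0.10, self.TIMES)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_labeling_division(self):
        assert kin.rate_lod(0.05, self.TIMES, f=0.5) == pytest.approx(
            2 * kin.rate_lod(0.05, self.TIMES, f=1.0), rel=1e-12)

    def test_positive(self):
        assert kin.rate_lod(1e-6, self.TIMES) > 0

    def test_degenerate_design(self):
        with pytest.raises(ValidationError):
            kin.rate_lod(0.05, [5, 5, 5])


class TestAmmoniumFromCombined:
    def test_equal(self):
        diff, flag = kin.ammonium_from_combined([5, 6], [5, 6])
        assert np.allclose(diff, [0, 0]) and not flag.any()

    def test_positive(self):
        diff, _ = kin.ammonium_from_combined([10.0], [4.0])
        assert diff[0] == pytest.approx(6.0)

    def test_negative_clipped_and_flagged(self):
        diff, flag = kin.ammonium_from_combined([3.0], [4.0])
        assert diff[0] == 0.0 and flag[0]

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            kin.ammonium_from_combined([1, 2], [1])


def _estimate(rate, lod, significant, **kw):
    defaults = dict(region="A", station="S", depth_m=100.0,
                    treatment="UREA_15N", replicate="r1", slope=rate,
                    slope_se=0.01, t_statistic=5.0,
                    p_one_sided=0.01 if significant else 0.4,
                    n_points=5)
    defaults.update(kw)
    return kin.RateEstimate(rate=rate, lod=lod, significant=significant,
                            **defaults)


class TestCensoring:
    def test_significant_unchanged(self):
        est = _estimate(1.2, 0.04, True)
        assert kin.censor_estimate(est, "lod").rate == 1.2

    def test_lod_policy(self):
        out = kin.censor_estimate(_estimate(0.01, 0.04, False), "lod")
        assert out.rate == 0.04 and out.censored

    def test_zero_policy(self):
        out = kin.censor_estimate(_estimate(0.01, 0.04, False), "zero")
        assert out.rate == 0.0 and out.censored

    def test_unknown_policy(self):
        with pytest.raises(ValidationError):
            kin.censor_estimate(_estimate(0.01, 0.04, False), "median")

    def test_published_lod_values_censor_exactly(self):
        # per-treatment detection limits used as censoring values
        for lod in (0.017, 0.040, 0.146):
            out = kin.censor_estimate(_estimate(0.001, lod, False), "lod")
            assert out.rate == lod


class TestReconcileDuplicates:
    def test_both_significant(self):
        out = kin.reconcile_duplicates(_estimate(1.0, 0.04, True),
                                       _estimate(2.0, 0.04, True))
        assert out.rate == pytest.approx(1.5)
        assert not out.censored

    def test_one_significant(self):
        out = kin.reconcile_duplicates(_estimate(1.0, 0.04, True),
                                       _estimate(0.01, 0.04, False))
        assert out.rate == pytest.approx(0.52)
        assert out.censored

    def test_none_significant(self):
        out = kin.reconcile_duplicates(_estimate(0.01, 0.04, False),
                                       _estimate(0.02, 0.04, False))
        assert out.rate == 0.0 and out.censored

    def test_metadata_mismatch(self):
        with pytest.raises(ValidationError):
            kin.reconcile_duplicates(_estimate(1.0, 0.04, True),
                                     _estimate(1.0, 0.04, True,
                                               treatment="NH4_15N"))

    def test_monotone_in_replicate_rates(self):
        base = kin.reconcile_duplicates(_estimate(1.0, 0.04, True),
                                        _estimate(2.0, 0.04, True))
        bigger = kin.reconcile_duplicates(_estimate(1.5, 0.04, True),
                                          _estimate(2.0, 0.04, True))
        assert bigger.rate >= base.rate


class TestPercentUreaOxidation:
    def test_symmetry(self):
        assert kin.percent_urea_oxidation(0.7, 0.7) == pytest.approx(50.0)

    def test_zero_urea(self):
        assert kin.percent_urea_oxidation(0.0, 1.0) == 0.0

    def test_ninety_percent(self):
        assert kin.percent_urea_oxidation(0.9, 0.1) == pytest.approx(90.0)

    def test_both_zero_missing(self):
        assert math.isnan(kin.percent_urea_oxidation(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            kin.percent_urea_oxidation(-0.1, 1.0)


class TestEstimateRate:
    def test_full_chain_scale_covariance(self):
        rng = np.random.default_rng(11)
        t = np.array([0, 6, 12, 18, 24.0])
        y = rng.normal(0.02 * t, 0.05)
        a = kin.estimate_rate(make_series(t, y), noise_sd=0.05)
        b = kin.estimate_rate(make_series(t, 3 * y), noise_sd=0.15)
        assert b.rate == pytest.approx(3 * a.rate, rel=1e-10)
        assert b.lod == pytest.approx(3 * a.lod, rel=1e-10)
        assert b.significant == a.significant

    def test_pooled_residual_sd(self):
        fits = [kin.fit_slope(make_series([0, 6, 12, 18, 24],
                                          [0, 1, 2.1, 2.9, 4.2])),
                kin.fit_slope(make_series([0, 6, 12, 18, 24],
                                          [0, 0.9, 2.0, 3.1, 3.8]))]
        pooled = kin.pooled_residual_sd(fits)
        expected = math.sqrt(sum(f.residual_sd ** 2 * 3 for f in fits) / 6)
        assert pooled == pytest.approx(expected, rel=1e-12)
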