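"""Dichotomization, autocovariance estimation, and AR(1) parameter fitting."""

import math

import numpy as np
import pytest

from cgmplan import (
    ARParams,
    BinarySeries,
    CGMTrace,
    FitSettings,
    GLYCEMIC_RANGES,
    GlycemicRange,
    SimulationConfig,
    AutocovEstimate,
    dichotomize,
    fit_alpha,
    fit_subject,
    population_params,
    sample_autocov,
    sd_error,
    simulate_traces,
    time_in_metric,
    to_cgm_trace,
)

GLUCOSE = [69.9, 70.0, 180.0, 53.9]


def make_trace(values, **kw):
    return CGMTrace(np.asarray(values, dtype=float), **kw)


class TestDichotomize:
    @pytest.mark.parametrize(
        "range_name, expected",
        [
            ("tbr", [1, 0, 0, 1]),   # strictly below 70: a reading of 70.0 is in range
            ("l2h", [0, 0, 0, 1]),   # level-2 hypoglycemia, strictly below 54
            ("tir", [0, 1, 0, 0]),   # [70, 180): 180.0 counts as above range
            ("tar", [0, 0, 1, 0]),
        ],
    )
    def test_threshold_conventions(self, range_name, expected):
        bits = dichotomize(make_trace(GLUCOSE), GLYCEMIC_RANGES[range_name])
        assert bits.bits.tolist() == expected

    def test_full_line_range_marks_everything(self):
        rng = GlycemicRange(-math.inf, math.inf)
        bits = dichotomize(make_trace(GLUCOSE), rng)
        assert bits.bits.tolist() == [1, 1, 1, 1]

    def test_range_fractions_partition_unity(self):
        rng = np.random.default_rng(7)
        g = make_trace(rng.uniform(40, 400, size=500))
        total = sum(
            time_in_metric(dichotomize(g, GLYCEMIC_RANGES[name]))
            for name in ("tbr", "tir", "tar")
        )
        assert total == pytest.approx(1.0)

    def test_invalid_glucose_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            make_trace([100.0, 90.0, math.nan, 80.0])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            GlycemicRange(180, 70)


class TestTimeInMetric:
    def test_prefix_means(self):
        bits = BinarySeries([1, 0, 0, 1])
        assert time_in_metric(bits) == 0.5
        assert time_in_metric(bits, 1) == 1.0
        assert time_in_metric(bits, 3) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n", [0, 5, -1])
    def test_out_of_bounds_prefix_rejected(self, n):
        with pytest.raises(ValueError):
            time_in_metric(BinarySeries([1, 0, 0, 1]), n)


class TestSampleAutocov:
    def test_hand_computed_values(self):
        est = sample_autocov(BinarySeries([1, 0, 0, 1]), max_lag=2)
        assert est.cov_values[0] == pytest.approx(1 / 3)     # (N-1)-denominator variance
        assert est.cov_values[1] == pytest.approx(-0.125)    # denominator N-1-1 = 2
        assert est.normalized[0] == 1.0

    def test_lag_zero_is_unbiased_sample_variance(self):
        rng = np.random.default_rng(11)
        x = (rng.random(300) < 0.3).astype(int)
        est = sample_autocov(BinarySeries(x), max_lag=5)
        assert est.cov_values[0] == pytest.approx(np.var(x, ddof=1), rel=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sample_autocov(BinarySeries([1, 1, 1, 1, 1]), max_lag=2)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            sample_autocov(BinarySeries([1, 0, 1, 0]), max_lag=3)

    def test_segments_pool_without_bridging(self):
        rng = np.random.default_rng(3)
        a = (rng.random(40) < 0.4).astype(int)
        b = (rng.random(25) < 0.4).astype(int)
        est = sample_autocov([BinarySeries(a), BinarySeries(b)], max_lag=3)

        mean = np.concatenate([a, b]).mean()
        for tau in range(4):
            total = sum(
                float((x[: len(x) - tau] - mean) @ (x[tau:] - mean))
                for x in (a.astype(float), b.astype(float))
            )
            pairs = (len(a) - tau) + (len(b) - tau)
            assert est.cov_values[tau] == pytest.approx(total / (pairs - 1), rel=1e-12)

    def test_single_segment_list_equals_plain_call(self):
        bits = BinarySeries([1, 0, 0, 1, 1, 0, 1, 0])
        a = sample_autocov(bits, max_lag=3)
        b = sample_autocov([bits], max_lag=3)
        np.testing.assert_allclose(a.cov_values, b.cov_values)

    def test_long_series_decay_matches_simulation_alpha(self):
        config = SimulationConfig.from_targets(0.3, 0.6, n_samples=60000, n_rep=1, seed=5)
        bits = simulate_traces(config)[0]
        est = sample_autocov(bits, max_lag=3)
        se = 1 / math.sqrt(len(bits))
        for tau in (1, 2, 3):
            assert est.normalized[tau] == pytest.approx(0.6**tau, abs=4 * se)


def exact_autocov(alpha: float, max_lag: int = 50, variance: float = 0.04,
                  n: int = 10000) -> AutocovEstimate:
    lags = np.arange(max_lag + 1)
    norm = alpha**lags.astype(float)
    return AutocovEstimate(lags, variance * norm, norm, n, n - lags)


class TestFitAlpha:
    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.86, 0.99])
    def test_exact_recovery_on_noiseless_decay(self, alpha):
        fit = fit_alpha(exact_autocov(alpha))
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert not fit.nonpositive_tail

    def test_white_noise_returns_zero(self):
        fit = fit_alpha(exact_autocov(0.0))
        assert fit.alpha == 0.0
        assert fit.nonpositive_tail  # every lag >= 1 is non-positive

    def test_negative_tail_returns_zero_with_flag(self):
        lags = np.arange(6)
        norm = np.array([1.0, -0.1, -0.05, -0.02, 0.0, -0.01])
        est = AutocovEstimate(lags, 0.04 * norm, norm, 100, 100 - lags)
        fit = fit_alpha(est)
        assert fit.alpha == 0.0 and fit.nonpositive_tail

    def test_requires_three_lags(self):
        est = exact_autocov(0.5, max_lag=1)
        with pytest.raises(ValueError):
            fit_alpha(est)

    def test_weighting_scheme_is_configurable(self):
        # corrupt one long lag; pair weighting discounts it more than uniform
        est = exact_autocov(0.8, max_lag=20, n=30)
        est.normalized[20] = 0.9
        est.cov_values[20] = 0.04 * 0.9
        fit_pairs = fit_alpha(est, FitSettings(weights="pairs"))
        fit_unif = fit_alpha(est, FitSettings(weights="uniform"))
        assert abs(fit_pairs.alpha - 0.8) < abs(fit_unif.alpha - 0.8)


class TestFitSubject:
    def test_all_in_range_trace_is_degenerate(self):
        trace = make_trace(np.full(100, 120.0))
        fit = fit_subject(trace, GLYCEMIC_RANGES["tbr"])
        assert fit.degenerate and fit.p_hat == 0.0
        assert math.isnan(fit.alpha_hat)

    def test_sigma2_consistent_with_p_hat(self):
        # 47 hypoglycemic samples out of 1000: p_hat = 0.047, sigma2 rounds to 0.045
        g = np.full(1000, 120.0)
        g[: 47] = 60.0
        rng = np.random.default_rng(0)
        rng.shuffle(g)
        fit = fit_subject(make_trace(g), GLYCEMIC_RANGES["tbr"])
        assert fit.p_hat == pytest.approx(0.047)
        assert round(fit.sigma2_hat, 3) == 0.045

    def test_parameter_recovery_on_simulated_trace(self):
        true = ARParams(0.3, 0.5)
        config = SimulationConfig.from_targets(0.3, 0.5, n_samples=20000, n_rep=1, seed=2)
        trace = to_cgm_trace(simulate_traces(config)[0], GLYCEMIC_RANGES["tbr"])
        fit = fit_subject(trace, GLYCEMIC_RANGES["tbr"])
        assert abs(fit.p_hat - 0.3) < 3 * sd_error(20000, true)
        assert fit.alpha_hat == pytest.approx(0.5, abs=0.05)

    def test_segments_of_one_subject_are_pooled(self):
        g = np.full(60, 120.0)
        g[10:20] = 60.0
        traces = [make_trace(g[:30], subject_id="s"), make_trace(g[30:], subject_id="s")]
        fit = fit_subject(traces, GLYCEMIC_RANGES["tbr"], FitSettings(max_lag=5))
        assert fit.p_hat == pytest.approx(10 / 60)
        assert fit.n_samples == 60


class TestPopulationParams:
    @staticmethod
    def fake_fit(p, a):
        from cgmplan import SubjectFit

        return SubjectFit("x", p, a, p * (1 - p))

    def test_default_rules_mean_and_p95(self):
        fits = [self.fake_fit(0.02, 0.8), self.fake_fit(0.06, 0.9)]
        pop = population_params(fits)
        assert pop.p_h == pytest.approx(0.04)
        assert pop.alpha == pytest.approx(0.895)  # interpolated 95th percentile

    def test_singleton_returns_own_values(self):
        pop = population_params([self.fake_fit(0.1, 0.7)])
        assert (pop.p_h, pop.alpha) == (0.1, 0.7)

    def test_constant_alphas_invariant_to_percentile(self):
        fits = [self.fake_fit(p, 0.85) for p in (0.01, 0.05, 0.2)]
        assert population_params(fits).alpha == 0.85

    def test_degenerate_fits_excluded(self):
        from cgmplan import SubjectFit

        fits = [
            SubjectFit("a", 0.0, math.nan, 0.0, degenerate=True),
            self.fake_fit(0.1, 0.8),
        ]
        assert population_params(fits).p_h == 0.1
        with pytest.raises(ValueError):
            population_params([fits[0]])
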