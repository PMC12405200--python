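import numpy as np
import pytest

from nabstat import (
    NeutralizationCurve,
    NoiseModel,
    TWOFOLD_SERIES,
    check_convergence,
    estimate_hill_mcmc,
    estimate_linear_bootstrap,
    estimate_threshold,
    simulate_curve,
)
from nabstat.errors import (
    BelowRangeError,
    BracketNotFoundError,
    ConvergenceError,
    CurveError,
)
from nabstat.estimators import McmcSettings, ND50Estimate
from nabstat.model import Dilution


def curve_from_means(fractions, means):
    """Single-replicate curve, fractions given most concentrated first."""
    return NeutralizationCurve(fractions, [[m] for m in means], "t")


class TestThreshold:
    def test_first_mean_below_half_scanning_from_dilute_end(self):
        # dilute-first means [0.8, 0.6, 0.45, 0.3, 0.1] -> 1/16
        c = curve_from_means(
            [1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64], [0.1, 0.3, 0.45, 0.6, 0.8]
        )
        est = estimate_threshold(c)
        assert est.point.fraction == 1 / 16
        assert est.ci_low is None
        assert "no_uncertainty" in est.diagnostics["flags"]

    def test_all_means_above_half_is_below_range(self):
        c = curve_from_means([1 / 4, 1 / 8], [0.6, 0.9])
        with pytest.raises(BelowRangeError):
            estimate_threshold(c)

    def test_all_means_below_half_right_censored(self):
        c = curve_from_means([1 / 4, 1 / 8, 1 / 16], [0.1, 0.2, 0.4])
        est = estimate_threshold(c)
        assert est.point.fraction == 1 / 16  # most dilute tested
        assert "right-censored" in est.diagnostics["flags"]

    def test_point_is_a_tested_dilution(self, noisy_curve):
        est = estimate_threshold(noisy_curve)
        assert est.point.fraction in [d.fraction for d in noisy_curve.dilutions]


class TestLinearBootstrap:
    def test_hand_interpolation_on_log2_axis(self):
        # (1/32, 0.6) and (1/16, 0.4): crossing at log2 midpoint -4.5
        c = curve_from_means([1 / 16, 1 / 32], [0.4, 0.6])
        est = estimate_linear_bootstrap(c)
        assert est.point.log2_value == pytest.approx(-4.5, abs=1e-12)
        assert est.point.fraction == pytest.approx(2 ** -4.5, rel=1e-12)

    def test_degenerate_replicates_give_zero_width(self):
        c = NeutralizationCurve([1 / 16, 1 / 32], [[0.4, 0.4], [0.6, 0.6]], "t")
        est = estimate_linear_bootstrap(c)
        assert est.diagnostics["n_combinations"] == 4
        assert est.width_log2 == 0.0
        assert est.ci_low.fraction == est.point.fraction == est.ci_high.fraction

    def test_monotone_curve_without_crossing(self):
        c = curve_from_means([1 / 4, 1 / 8, 1 / 16], [0.55, 0.7, 0.9])
        with pytest.raises(BracketNotFoundError):
            estimate_linear_bootstrap(c)

    def test_zero_slope_pairs_skipped(self):
        c = NeutralizationCurve([1 / 16, 1 / 32], [[0.5, 0.3], [0.7, 0.5]], "t")
        est = estimate_linear_bootstrap(c)
        assert est.diagnostics["zero_slope_pairs_skipped"] == 1
        assert est.diagnostics["n_combinations"] == 3

    def test_point_between_bracketing_dilutions(self):
        c = NeutralizationCurve(
            [1 / 16, 1 / 32], [[0.42, 0.38, 0.45], [0.61, 0.55, 0.66]], "t"
        )
        est = estimate_linear_bootstrap(c)
        assert 1 / 32 <= est.point.fraction <= 1 / 16
        assert est.ci_low.fraction <= est.point.fraction <= est.ci_high.fraction

    def test_crossing_nearest_dilute_end_selected(self):
        # two crossings; the one nearest the dilute end wins
        c = curve_from_means(
            [1 / 4, 1 / 8, 1 / 16, 1 / 32], [0.1, 0.6, 0.45, 0.8]
        )
        est = estimate_linear_bootstrap(c)
        assert est.diagnostics["bracket"] == (1 / 32, 1 / 16)
        assert len(est.diagnostics["all_crossings"]) == 2

    def test_linear_axis_option(self):
        c = curve_from_means([1 / 16, 1 / 32], [0.4, 0.6])
        est = estimate_linear_bootstrap(c, axis="linear")
        mid = (1 / 32 + 1 / 16) / 2
        assert est.point.fraction == pytest.approx(mid, rel=1e-12)


class TestHillMcmc:
    def test_noiseless_curve_recovers_truth(self, noiseless_curve):
        """Zero-noise triplicates at the standard 7-step series: posterior
        mean ND50 lands on the generating 1/16 and the sampler converges."""
        est = estimate_hill_mcmc(noiseless_curve, settings=McmcSettings(seed=3))
        assert est.point.log2_value == pytest.approx(-4.0, abs=0.05)
        assert est.diagnostics["r_hat"] < 1.01
        assert check_convergence(est)

    def test_interval_brackets_point_and_draws_shape(self, noisy_curve, fast_mcmc):
        est = estimate_hill_mcmc(noisy_curve, settings=fast_mcmc)
        assert est.ci_low.fraction <= est.point.fraction <= est.ci_high.fraction
        assert est.draws.shape == (fast_mcmc.chains * fast_mcmc.draws,)
        assert np.all(est.draws > 0)

    def test_deterministic_given_seed(self, noisy_curve, fast_mcmc):
        a = estimate_hill_mcmc(noisy_curve, settings=fast_mcmc)
        b = estimate_hill_mcmc(noisy_curve, settings=fast_mcmc)
        assert np.array_equal(a.draws, b.draws)

    def test_extrapolates_beyond_tested_range(self, fast_mcmc):
        """Truth 1/32 tested only at 1/4-1/16: interpolators fail but the
        Hill fit still returns a finite, wider-uncertainty estimate."""
        from nabstat import HillParams

        c = simulate_curve(
            HillParams(1 / 32), [1 / 4, 1 / 8, 1 / 16], 3, NoiseModel(0.10), seed=8
        )
        with pytest.raises(BracketNotFoundError):
            estimate_linear_bootstrap(c)
        est = estimate_hill_mcmc(c, settings=fast_mcmc)
        assert est.point.fraction < 1 / 16  # beyond the tested range
        assert est.width_log2 > 0.3  # honest extra uncertainty

    def test_non_positive_te_rejected(self, fast_mcmc):
        c = NeutralizationCurve([1 / 4, 1 / 8], [[0.0], [0.5]], "t")
        with pytest.raises(CurveError):
            estimate_hill_mcmc(c, settings=fast_mcmc)

    def test_methods_agree_on_noiseless_data(self, noiseless_curve, fast_mcmc):
        """With b=0 and no noise all three estimators point at 1/16."""
        thr = estimate_threshold(noiseless_curve)
        boot = estimate_linear_bootstrap(noiseless_curve)
        mcmc = estimate_hill_mcmc(noiseless_curve, settings=fast_mcmc)
        assert abs(thr.point.log2_value - (-4.0)) <= 1.0  # within one step
        assert boot.point.log2_value == pytest.approx(-4.0, abs=1e-9)
        assert abs(mcmc.point.log2_value - boot.point.log2_value) < 0.05


class TestCheckConvergence:
    def _est(self, **diag):
        return ND50Estimate(method="hill_mcmc", point=Dilution(0.1), diagnostics=diag)

    def test_pass_below_threshold(self):
        assert check_convergence(self._est(r_hat=1.005))

    def test_fail_at_threshold(self):
        assert not check_convergence(self._est(r_hat=1.02))

    def test_missing_diagnostic_is_an_error(self):
        with pytest.raises(ConvergenceError):
            check_convergence(self._est())
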