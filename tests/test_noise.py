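"""Residual extraction, stable ECF fitting, survival curves and tail slopes."""

import numpy as np
import pytest
from scipy import stats

import levylangevin as ll
from levylangevin.noise import (
    EstimationError,
    ResidualSet,
    empirical_ccdf,
    mcculloch_initial,
    pool_residuals,
    tail_slope,
)


class TestExtractResiduals:
    def test_noise_free_residuals_are_zero(self):
        model = ll.DriftModel(0.4, 1.0)
        ts = ll.simulate_langevin(model, None, 100, x0=8.0, burn_in=0)
        res = ll.extract_residuals(ts, model)
        assert len(res) == len(ts) - 1
        np.testing.assert_allclose(res.xi, 0.0, atol=1e-12)

    def test_true_model_inverts_simulation_exactly(self):
        # with the generating drift supplied, xi equals the injected draws
        model = ll.DriftModel(0.3, 0.0)
        noise = ll.centered_noise(1.5, 0.0, 1.0)
        rng = np.random.default_rng(6)
        draws = ll.stable_sample(noise, 500, seed=rng)
        x = np.empty(501)
        x[0] = 0.0
        for t in range(500):
            x[t + 1] = x[t] - 0.3 * x[t] + draws[t]
        res = ll.extract_residuals(ll.TimeSeries(x), model)
        np.testing.assert_allclose(res.xi, draws, atol=1e-12)

    def test_fitted_model_residuals_match_fresh_draws(self):
        noise = ll.centered_noise(1.5, 0.0, 1.0)
        ts = ll.simulate_langevin(ll.DriftModel(0.3, 0.0), noise, 10_000, seed=8)
        model = ll.LinearDriftEstimator().fit(ts).model_
        res = ll.extract_residuals(ts, model)
        fresh = ll.stable_sample(noise, 10_000, seed=88)
        assert stats.ks_2samp(res.xi, fresh).pvalue > 0.05

    def test_magnitudes_and_pooling(self):
        a = ResidualSet(np.array([-1.0, 2.0]), network_id="n")
        b = ResidualSet(np.array([3.0]), network_id="n")
        np.testing.assert_array_equal(a.magnitudes, [1.0, 2.0])
        pooled = pool_residuals([a, b])
        assert len(pooled) == 3 and pooled.network_id == "n"

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            ll.extract_residuals(np.array([1.0]), ll.DriftModel(0.3, 0.0))


class TestStableECFEstimator:
    """The three closed-form special cases are generated by transforms that
    never touch the package's own sampler."""

    def test_gaussian_special_case(self, rng):
        est = ll.StableECFEstimator().fit(rng.standard_normal(10_000))
        assert est.alpha_ == pytest.approx(2.0, abs=0.05)
        # Normal(0, 1) is the stable law with gamma = 1/sqrt(2)
        assert est.gamma_ == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_cauchy_special_case(self, rng):
        x = np.tan(np.pi * (rng.uniform(size=10_000) - 0.5))
        est = ll.StableECFEstimator().fit(x)
        assert est.alpha_ == pytest.approx(1.0, abs=0.05)
        assert est.beta_ == pytest.approx(0.0, abs=0.1)

    def test_levy_special_case(self, rng):
        x = 1.0 / rng.standard_normal(10_000) ** 2
        est = ll.StableECFEstimator().fit(x)
        assert est.alpha_ == pytest.approx(0.5, abs=0.05)
        assert est.beta_ == pytest.approx(1.0, abs=0.15)
        assert est.gamma_ == pytest.approx(1.0, abs=0.1)

    def test_consistency_over_alpha_grid(self):
        # mean absolute error of alpha-hat at n = 10^4 stays within 0.05
        for alpha in (1.0, 1.2, 1.5, 1.8, 2.0):
            errs = []
            for s in range(20):
                x = ll.stable_sample(
                    ll.StableParams(alpha, 0.0, 1.0, 0.0), 10_000,
                    seed=np.random.default_rng([int(alpha * 10), s]),
                )
                errs.append(abs(ll.StableECFEstimator().fit(x).alpha_ - alpha))
            assert np.mean(errs) <= 0.05, f"alpha={alpha}: {np.mean(errs)}"

    def test_scale_and_location_recovery(self):
        x = ll.stable_sample(ll.StableParams(1.4, 0.3, 2.5, -1.0), 20_000, seed=31)
        p = ll.estimate_stable_params(x)
        assert p.alpha == pytest.approx(1.4, abs=0.05)
        assert p.beta == pytest.approx(0.3, abs=0.15)
        assert p.gamma == pytest.approx(2.5, rel=0.05)
        assert p.delta == pytest.approx(-1.0, abs=0.25)
        assert p.parameterization == "S1"

    def test_floor_and_degenerate_inputs(self):
        with pytest.raises(EstimationError):
            ll.StableECFEstimator().fit(np.random.default_rng(0).normal(size=100))
        with pytest.raises(EstimationError):
            ll.StableECFEstimator().fit(np.ones(500))

    def test_mcculloch_initial_sane(self, rng):
        a0, b0, g0, d0 = mcculloch_initial(rng.standard_normal(50_000))
        assert a0 > 1.8 and abs(b0) < 0.2 and abs(d0) < 0.05


class TestSurvivalCurve:
    def test_survival_by_definition(self):
        curve = empirical_ccdf([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(curve.survival, [1.0, 0.75, 0.5, 0.25])
        assert np.all(curve.survival > 0)

    def test_ties_share_higher_value(self):
        curve = empirical_ccdf([2.0, 2.0, 2.0])
        np.testing.assert_allclose(curve.survival, [1.0, 1.0, 1.0])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            empirical_ccdf([])
        with pytest.raises(ValueError):
            empirical_ccdf([-1.0, 2.0])

    def test_round_trip_frame(self):
        df = empirical_ccdf([1.0, 5.0, 2.0]).to_frame()
        assert list(df.columns) == ["magnitude", "survival"]
        assert df["magnitude"].is_monotonic_increasing


class TestTailSlope:
    def test_exact_power_law_grid(self):
        # survival F = m^-1.5 sampled on a grid: fitting a line to a line
        m = np.logspace(0, 2, 2000)
        curve = ll.SurvivalCurve(magnitudes=m, survival=m ** -1.5)
        fit = tail_slope(curve, tail_fraction=0.5)
        assert fit.alpha_tail == pytest.approx(1.5, abs=1e-9)
        assert fit.power_law

    def test_pareto_draws_recover_exponent(self, rng):
        m = rng.pareto(1.5, 100_000) + 1.0
        fit = tail_slope(empirical_ccdf(m), tail_fraction=0.1)
        assert fit.alpha_tail == pytest.approx(1.5, abs=0.1)
        assert fit.hill_alpha == pytest.approx(1.5, abs=0.1)

    def test_stable_magnitudes_recover_alpha(self):
        x = ll.stable_sample(ll.StableParams(1.3, 0.0, 1.0, 0.0), 100_000, seed=44)
        fit = tail_slope(empirical_ccdf(np.abs(x)), tail_fraction=0.1)
        assert fit.alpha_tail == pytest.approx(1.3, abs=0.15)

    def test_gaussian_tail_flagged_as_non_power_law(self, rng):
        fit = tail_slope(empirical_ccdf(np.abs(rng.standard_normal(100_000))), 0.1)
        assert fit.alpha_tail > 2.0
        assert not fit.power_law

    def test_input_validation(self):
        curve = empirical_ccdf(np.arange(1.0, 100.0))
        with pytest.raises(ValueError):
            tail_slope(curve, tail_fraction=0.7)
        with pytest.raises(ValueError):
            tail_slope(curve, tail_fraction=0.1)  # only ~9 tail points


class TestScaleInvariance:
    """alpha is dimensionless: rescaling the residuals must not move it.

    This is the testable content of the law pdf(|y|) ~ |y|^(-1-alpha) being
    preserved under y = k xi, i.e. the sampling-interval invariance of the
    tail exponent.
    """

    def test_both_estimators_invariant_under_rescaling(self):
        x = ll.stable_sample(ll.StableParams(1.3, 0.0, 1.0, 0.0), 50_000, seed=77)
        base_ecf = ll.StableECFEstimator().fit(x).alpha_
        base_tail = tail_slope(empirical_ccdf(np.abs(x)), 0.1).alpha_tail
        for scale in (0.01, 7.3, 1000.0):
            assert ll.StableECFEstimator().fit(scale * x).alpha_ == pytest.approx(
                base_ecf, abs=0.02
            )
            assert tail_slope(
                empirical_ccdf(np.abs(scale * x)), 0.1
            ).alpha_tail == pytest.approx(base_tail, abs=1e-6)

    def test_ecf_and_tail_estimates_agree_for_moderate_alpha(self):
        # the two routes to alpha agree within 0.2 below alpha ~ 1.6
        for alpha in (1.2, 1.5):
            x = ll.stable_sample(
                ll.StableParams(alpha, 0.0, 1.0, 0.0), 100_000,
                seed=np.random.default_rng([7, int(10 * alpha)]),
            )
            ecf = ll.StableECFEstimator().fit(x).alpha_
            tail = tail_slope(empirical_ccdf(np.abs(x)), 0.1).alpha_tail
            assert abs(ecf - tail) < 0.2
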