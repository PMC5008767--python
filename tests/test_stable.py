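"""Stable-law numerics: characteristic function, sampler, pdf/cdf inversion.

The independent oracles are closed-form special cases (normal, Cauchy, Levy),
direct transforms of uniforms/normals, and scipy's levy_stable distribution,
which is never used inside the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from levylangevin.stable import (
    ParameterError,
    StableParams,
    stable_cdf,
    stable_ccdf,
    stable_cf,
    stable_pdf,
    stable_sample,
)

PARAM_GRID = [
    (a, b) for a in (0.6, 1.0, 1.3, 1.7, 2.0) for b in (-0.5, 0.0, 1.0)
]

valid_params = st.builds(
    StableParams,
    alpha=st.floats(0.3, 2.0),
    beta=st.floats(-1.0, 1.0),
    gamma=st.floats(0.05, 20.0),
    delta=st.floats(-50.0, 50.0),
)


class TestStableParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0.0, beta=0, gamma=1, delta=0),
            dict(alpha=2.5, beta=0, gamma=1, delta=0),
            dict(alpha=1.5, beta=1.5, gamma=1, delta=0),
            dict(alpha=1.5, beta=0, gamma=0.0, delta=0),
            dict(alpha=1.5, beta=0, gamma=1, delta=math.inf),
            dict(alpha=1.5, beta=0, gamma=1, delta=0, parameterization="S2"),
        ],
    )
    def test_domain_validation(self, kwargs):
        with pytest.raises(ParameterError):
            StableParams(**kwargs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(valid_params)
    def test_s0_s1_conversion_is_involution(self, p):
        back = p.to_s0().to_s1()
        assert back.alpha == p.alpha and back.beta == p.beta
        assert back.delta == pytest.approx(p.delta, rel=1e-9, abs=1e-9)

    def test_alpha2_location_identical_in_both_forms(self):
        # at alpha = 2 the skew term of the CF vanishes (tan(pi) = 0)
        p = StableParams(2.0, 0.7, 1.3, 0.5)
        assert p.to_s0().delta == pytest.approx(0.5)


class TestCharacteristicFunction:
    def test_cf_at_zero_is_one(self):
        for a, b in PARAM_GRID:
            assert stable_cf(0.0, StableParams(a, b, 2.0, -1.0)) == pytest.approx(1.0)

    def test_gaussian_and_cauchy_cases(self):
        # standard normal-family member: exp(-(gamma t)^2); Cauchy: exp(-gamma|t|)
        assert stable_cf(1.0, StableParams(2, 0, 1, 0)) == pytest.approx(math.exp(-1))
        assert stable_cf(1.0, StableParams(1, 0, 1, 0)) == pytest.approx(math.exp(-1))

    def test_location_shift_multiplies_by_phase(self):
        p = StableParams(1.4, 0.3, 2.0, 0.0)
        q = StableParams(1.4, 0.3, 2.0, 1.7)
        t = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(
            stable_cf(t, q), stable_cf(t, p) * np.exp(1j * 1.7 * t), rtol=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(valid_params, st.floats(-100.0, 100.0))
    def test_modulus_bound_and_conjugate_symmetry(self, p, t):
        v = stable_cf(t, p)
        assert abs(v) <= 1.0 + 1e-12
        assert stable_cf(-t, p) == pytest.approx(np.conj(v), rel=1e-12, abs=1e-12)

    def test_s0_input_converted(self):
        p1 = StableParams(1.5, 0.5, 1.0, 0.0, "S1")
        p0 = p1.to_s0()
        t = np.array([-2.0, 0.5, 3.0])
        np.testing.assert_allclose(stable_cf(t, p0), stable_cf(t, p1), rtol=1e-12)


class TestSampler:
    def test_empty_and_negative(self):
        p = StableParams(1.5, 0, 1, 0)
        assert stable_sample(p, 0, seed=1).size == 0
        with pytest.raises(ValueError):
            stable_sample(p, -1, seed=1)

    def test_reproducible(self):
        p = StableParams(1.2, 0.4, 1, 0)
        np.testing.assert_array_equal(
            stable_sample(p, 100, seed=5), stable_sample(p, 100, seed=5)
        )

    def test_alpha2_matches_gaussian_variance(self):
        # alpha = 2 with scale gamma is Normal(delta, 2 gamma^2)
        s = stable_sample(StableParams(2, 0, 1, 0), 100_000, seed=11)
        assert s.std() == pytest.approx(math.sqrt(2), rel=0.02)

    def test_cauchy_case_against_closed_form_cdf(self):
        s = stable_sample(StableParams(1, 0, 1, 0), 10_000, seed=3)
        pv = stats.kstest(s, lambda x: 0.5 + np.arctan(x) / np.pi).pvalue
        assert pv > 0.05

    def test_levy_case_against_independent_generator(self):
        # alpha=0.5, beta=1 equals delta + gamma / Z^2 for standard normal Z
        rng = np.random.default_rng(17)
        ref = 0.3 + 2.0 / rng.standard_normal(20_000) ** 2
        s = stable_sample(StableParams(0.5, 1, 2.0, 0.3), 20_000, seed=19)
        assert stats.ks_2samp(ref, s).pvalue > 0.01

    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_sample_agrees_with_own_cdf(self, alpha, beta):
        p = StableParams(alpha, beta, 1.0, 0.0)
        s = stable_sample(p, 1000, seed=int(alpha * 100 + beta * 10 + 1000))
        pv = stats.kstest(s, lambda x: stable_cdf(x, p)).pvalue
        assert pv > 0.01


class TestDensityAndDistribution:
    def test_closed_form_values(self):
        assert stable_pdf(0.0, StableParams(1, 0, 1, 0)) == pytest.approx(1 / math.pi)
        assert stable_pdf(0.0, StableParams(2, 0, 1, 0)) == pytest.approx(
            1 / (2 * math.sqrt(math.pi))
        )
        assert stable_ccdf(1.0, StableParams(1, 0, 1, 0)) == pytest.approx(0.25)

    def test_symmetric_ccdf_at_location_is_half(self):
        for a in (0.8, 1.0, 1.5, 2.0):
            assert stable_ccdf(0.7, StableParams(a, 0, 2.0, 0.7)) == pytest.approx(
                0.5, abs=1e-6
            )

    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_pdf_normalizes(self, alpha, beta):
        p = StableParams(alpha, beta, 1.0, 0.0)
        # symmetric log-spaced grid wide enough to capture heavy tails
        right = np.logspace(-3, 6, 400)
        grid = np.concatenate([-right[::-1], [0.0], right])
        mass = np.trapezoid(stable_pdf(grid, p), grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("alpha,beta", [(1.5, 0.0), (1.3, 0.5), (0.8, -0.5)])
    def test_matches_scipy_levy_stable(self, alpha, beta):
        # independent oracle: scipy's own integration of the same law (S1)
        p = StableParams(alpha, beta, 1.3, 0.4)
        x = np.array([-6.0, -1.0, 0.0, 0.8, 2.5, 8.0])
        ref_pdf = stats.levy_stable.pdf(x, alpha, beta, loc=0.4, scale=1.3)
        ref_cdf = stats.levy_stable.cdf(x, alpha, beta, loc=0.4, scale=1.3)
        np.testing.assert_allclose(stable_pdf(x, p), ref_pdf, atol=1e-6)
        np.testing.assert_allclose(stable_cdf(x, p), ref_cdf, atol=1e-6)

    def test_ccdf_monotone_and_bounded(self):
        p = StableParams(1.3, 0.5, 1.0, 0.0)
        x = np.linspace(-30, 30, 121)
        v = stable_ccdf(x, p)
        assert np.all(v >= 0) and np.all(v <= 1)
        assert np.all(np.diff(v) <= 1e-12)

    def test_pareto_tail_halving_ratio(self):
        # survival ~ x^-alpha far out, so ccdf(2x)/ccdf(x) -> 2^-alpha
        p = StableParams(1.5, 0, 1, 0)
        for x in (50.0, 100.0):
            ratio = stable_ccdf(2 * x, p) / stable_ccdf(x, p)
            assert ratio == pytest.approx(2 ** -1.5, rel=0.01)

    def test_levy_branch_against_transform(self):
        # Levy(delta, gamma) == delta + gamma/Z^2: check CDF closed form
        p = StableParams(0.5, 1, 2.0, 1.0)
        x = np.array([1.5, 3.0, 10.0, 100.0])
        ref = stats.levy.cdf(x, loc=1.0, scale=2.0)
        np.testing.assert_allclose(stable_cdf(x, p), ref, rtol=1e-9)
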