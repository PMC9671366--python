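import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from cmpreg.distribution import (
    CMPParams,
    SeriesControl,
    SeriesConvergenceError,
    SeriesDivergenceError,
    ZICMPParams,
    cmp_log_pmf,
    cmp_moments,
    cmp_pmf,
    cmp_sample,
    log_normalizing_constant,
    zicmp_pmf,
    zicmp_sample,
)
from conftest import brute_force_log_z, brute_force_moments

# the CMP maximum-likelihood estimates on the packaged fatality table
LAM_HAT, NU_HAT = 0.33189, 1.55024


class TestNormalizingConstant:
    def test_poisson_case_is_exp_lambda(self):
        assert log_normalizing_constant(CMPParams(1.0, 1.0)) == pytest.approx(1.0, abs=1e-10)
        assert log_normalizing_constant(CMPParams(2.5, 1.0)) == pytest.approx(2.5, abs=1e-10)

    def test_vanishing_rate_leaves_only_first_term(self):
        assert log_normalizing_constant(CMPParams(1e-12, 2.0)) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_summation(self):
        expected = brute_force_log_z(LAM_HAT, NU_HAT)
        assert math.exp(expected) == pytest.approx(1.372, abs=5e-4)
        assert log_normalizing_constant(CMPParams(LAM_HAT, NU_HAT)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_geometric_boundary(self):
        # nu = 0 with lam < 1: Z = 1 / (1 - lam)
        assert log_normalizing_constant(CMPParams(0.5, 0.0)) == pytest.approx(
            math.log(2.0), abs=1e-10
        )

    def test_divergence_guard(self):
        with pytest.raises(SeriesDivergenceError):
            CMPParams(1.5, 0.0)

    def test_max_terms_exhaustion(self):
        control = SeriesControl(rel_tol=1e-12, max_terms=100)
        with pytest.raises(SeriesConvergenceError):
            log_normalizing_constant(CMPParams(5.0, 0.05), control)


class TestPmf:
    def test_zero_count_is_reciprocal_z(self):
        p = CMPParams(LAM_HAT, NU_HAT)
        assert cmp_log_pmf(0, p) == pytest.approx(-log_normalizing_constant(p), abs=1e-12)

    def test_poisson_case(self):
        assert cmp_log_pmf(2, CMPParams(1.0, 1.0)) == pytest.approx(
            math.log(math.exp(-1.0) / 2.0), abs=1e-10
        )

    def test_against_summation_oracle(self):
        log_z = brute_force_log_z(LAM_HAT, NU_HAT)
        assert cmp_log_pmf(1, CMPParams(LAM_HAT, NU_HAT)) == pytest.approx(
            math.log(LAM_HAT) - log_z, abs=1e-10
        )

    @pytest.mark.parametrize("nu", [0.3, 0.7, 1.0, 1.55, 3.0])
    @pytest.mark.parametrize("lam", [0.05, 0.33, 1.0, 2.2, 5.0])
    def test_normalization_grid(self, lam, nu):
        y = np.arange(400)
        assert cmp_pmf(y, CMPParams(lam, nu)).sum() == pytest.approx(1.0, abs=1e-8)

    def test_poisson_reduction_to_1e10(self):
        for lam in (0.3, 1.0, 4.0):
            y = np.arange(21)
            ours = cmp_log_pmf(y, CMPParams(lam, 1.0))
            assert np.max(np.abs(ours - poisson.logpmf(y, lam))) < 1e-10

    @given(
        lam=st.floats(0.05, 5.0),
        nu=st.floats(0.3, 3.0),
        pi=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_zicmp_normalizes_for_any_parameters(self, lam, nu, pi):
        y = np.arange(400)
        total = zicmp_pmf(y, ZICMPParams(CMPParams(lam, nu), pi)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_zicmp_degenerate_and_mixture_cases(self):
        base = CMPParams(LAM_HAT, NU_HAT)
        assert zicmp_pmf(0, ZICMPParams(base, 1.0)) == pytest.approx(1.0)
        assert zicmp_pmf(3, ZICMPParams(base, 1.0)) == pytest.approx(0.0)
        z = math.exp(brute_force_log_z(*[LAM_HAT, NU_HAT]))
        assert zicmp_pmf(0, ZICMPParams(base, 0.5)) == pytest.approx(
            0.5 + 0.5 / z, abs=1e-10
        )
        # pi = 0 reduces to the plain CMP pmf
        y = np.arange(10)
        np.testing.assert_allclose(
            zicmp_pmf(y, ZICMPParams(base, 0.0)), cmp_pmf(y, base), atol=1e-14
        )


class TestMoments:
    def test_poisson_case_exact(self):
        mean, var = cmp_moments(CMPParams(2.0, 1.0), method="exact")
        assert mean == pytest.approx(2.0, abs=1e-8)
        assert var == pytest.approx(2.0, abs=1e-8)

    def test_exact_matches_oracle_and_differs_from_approx(self):
        mean, var = cmp_moments(CMPParams(LAM_HAT, NU_HAT), method="exact")
        o_mean, o_var = brute_force_moments(LAM_HAT, NU_HAT)
        assert mean == pytest.approx(o_mean, abs=1e-10)
        assert var == pytest.approx(o_var, abs=1e-10)
        assert mean == pytest.approx(0.302, abs=1e-3)
        a_mean, _ = cmp_moments(CMPParams(LAM_HAT, NU_HAT), method="approx")
        assert a_mean == pytest.approx(0.313, abs=1e-3)
        # at this small rate the asymptotic form is materially off the truth
        assert abs(a_mean - mean) > 5e-3

    def test_approx_rejects_nu_zero(self):
        with pytest.raises(ValueError):
            cmp_moments(CMPParams(0.5, 0.0), method="approx")

    def test_variance_to_mean_ratio_decreases_in_nu(self):
        ratios = []
        for nu in (0.5, 1.0, 1.5, 2.0):
            mean, var = cmp_moments(CMPParams(1.2, nu))
            ratios.append(var / mean)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestSampling:
    def test_determinism(self):
        p = CMPParams(0.8, 1.3)
        a = cmp_sample(3, p, seed=42)
        b = cmp_sample(3, p, seed=42)
        np.testing.assert_array_equal(a, b)
        zp = ZICMPParams(p, 0.4)
        np.testing.assert_array_equal(
            zicmp_sample(5, zp, seed=9), zicmp_sample(5, zp, seed=9)
        )

    def test_poisson_limit_mean(self):
        draws = cmp_sample(100_000, CMPParams(1.0, 1.0), seed=1)
        assert abs(draws.mean() - 1.0) < 4.0 * math.sqrt(1.0 / 100_000)

    def test_underdispersion_of_fitted_parameters(self):
        draws = cmp_sample(100_000, CMPParams(LAM_HAT, NU_HAT), seed=2)
        assert draws.var() / draws.mean() < 1.0

    def test_zero_inflated_zero_fraction(self):
        params = ZICMPParams(CMPParams(2.0, 1.0), 0.3)
        draws = zicmp_sample(100_000, params, seed=3)
        expected = 0.3 + 0.7 * math.exp(-2.0)
        se = math.sqrt(expected * (1 - expected) / 100_000)
        assert abs((draws == 0).mean() - expected) < 4.0 * se

    def test_all_zeros_when_pi_one(self):
        draws = zicmp_sample(1000, ZICMPParams(CMPParams(2.0, 1.0), 1.0), seed=4)
        assert not draws.any()

    def test_empirical_pmf_matches_model(self):
        params = ZICMPParams(CMPParams(1.5, 1.8), 0.25)
        n = 100_000
        draws = zicmp_sample(n, params, seed=5)
        values, counts = np.unique(draws, return_counts=True)
        probs = zicmp_pmf(values, params)
        expected = n * probs
        keep = expected >= 5
        mc_se = np.sqrt(n * probs * (1 - probs))
        assert np.all(np.abs(counts[keep] - expected[keep]) < 4.0 * mc_se[keep])


class TestParameterValidation:
    @pytest.mark.parametrize("lam,nu", [(-1.0, 1.0), (0.0, 1.0), (1.0, -0.1)])
    def test_invalid_cmp_params(self, lam, nu):
        with pytest.raises(ValueError):
            CMPParams(lam, nu)

    @pytest.mark.parametrize("pi", [-0.1, 1.1])
    def test_invalid_zero_mass(self, pi):
        with pytest.raises(ValueError):
            ZICMPParams(CMPParams(1.0, 1.0), pi)

    def test_series_control_validation(self):
        with pytest.raises(ValueError):
            SeriesControl(rel_tol=2.0)
        with pytest.raises(ValueError):
            SeriesControl(max_terms=10)
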