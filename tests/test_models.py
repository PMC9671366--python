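import numpy as np
import pandas as pd
import pytest

from cmpreg.design import DesignSet, THAILAND_CODING, build_design
from cmpreg.frequency import CountFrequencyTable
from cmpreg.models import (
    RankDeficiencyError,
    _make_objective,
    fit_cmp,
    fit_poisson,
    fit_zicmp,
    fit_zip,
    predict_mean,
)
from cmpreg.distribution import DEFAULT_CONTROL, CMPParams, ZICMPParams, cmp_sample, zicmp_sample


def _records(n, seed, **cols):
    rng = np.random.default_rng(seed)
    data = {}
    for name, levels in cols.items():
        data[name] = rng.choice(levels, size=n)
    return pd.DataFrame(data)


class TestBuildDesign:
    def test_column_counts(self):
        rec = _records(
            50,
            0,
            roadway_class=THAILAND_CODING.levels["roadway_class"],
            road_surface=THAILAND_CODING.levels["road_surface"],
            road_section=THAILAND_CODING.levels["road_section"],
            weather=THAILAND_CODING.levels["weather"],
            light=THAILAND_CODING.levels["light"],
            month=THAILAND_CODING.levels["month"],
        )
        rec["fatalities"] = 0
        rec.loc[0, "fatalities"] = 1
        six = ("roadway_class", "road_surface", "road_section", "weather", "light", "month")
        d = build_design(rec, count_terms=six, zero_terms=("month",))
        # 1 + 3 + 1 + 2 + 2 + 2 + 11 treatment-coded columns
        assert d.X.shape[1] == 22
        assert d.W.shape[1] == 12
        assert d.S.shape[1] == 1
        assert d.x_names[0] == "(Intercept)"

    def test_intercept_only_design(self):
        rec = pd.DataFrame({"fatalities": [0, 1, 2]})
        d = build_design(rec)
        for mat in (d.X, d.S, d.W):
            np.testing.assert_array_equal(mat, np.ones((3, 1)))

    def test_unknown_level_names_record(self):
        rec = pd.DataFrame({"fatalities": [0, 0], "month": ["January", "Smarch"]})
        with pytest.raises(ValueError, match="record 1.*Smarch"):
            build_design(rec, count_terms=("month",))

    def test_non_integer_outcome_rejected(self):
        rec = pd.DataFrame({"fatalities": [0.5, 1.0]})
        with pytest.raises(ValueError):
            build_design(rec)


class TestPoisson:
    def test_intercept_is_log_mean_to_machine_precision(self, freq, freq_design):
        fit = fit_poisson(freq_design)
        assert fit.beta[0] == pytest.approx(np.log(freq.mean), abs=1e-12)

    def test_constant_outcome(self):
        fit = fit_poisson(DesignSet.from_outcome([1, 1, 1, 1]))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_on_simulated_data(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(2.0, size=10_000)
        fit = fit_poisson(DesignSet.from_outcome(y))
        assert abs(fit.beta[0] - np.log(2.0)) < 4.0 * np.sqrt(1.0 / (2.0 * 10_000))
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-12)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.normal(size=2000)
        y = rng.poisson(np.exp(0.2 + 0.5 * x))
        X = np.column_stack([np.ones(2000), x])
        design = DesignSet(
            y=y, w=np.ones(2000), X=X, S=np.ones((2000, 1)), W=np.ones((2000, 1)),
            x_names=["(Intercept)", "x"], s_names=["(Intercept)"], w_names=["(Intercept)"],
        )
        ours = fit_poisson(design)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-7)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(ours.se_beta, ref.bse, rtol=1e-3)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_poisson(DesignSet.from_outcome([0, 0, 0]))

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        design = DesignSet(
            y=np.ones(10, dtype=int), w=np.ones(10), X=X,
            S=np.ones((10, 1)), W=np.ones((10, 1)),
            x_names=["(Intercept)", "a", "b"], s_names=["(Intercept)"], w_names=["(Intercept)"],
        )
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_poisson(design)


class TestCmp:
    def test_dispersion_estimate_near_zero_on_poisson_data(self):
        rng = np.random.default_rng(12)
        y = rng.poisson(1.0, size=10_000)
        fit = fit_cmp(DesignSet.from_outcome(y))
        assert abs(fit.delta[0]) < 3.0 * fit.se_delta[0]

    def test_nesting_improves_on_poisson(self, fixture_fits):
        assert fixture_fits["cmp"].loglik >= fixture_fits["poisson"].loglik - 1e-6

    def test_optimum_independent_of_start(self, freq_design):
        ref = fit_cmp(freq_design)
        for shift in (-0.5, 0.5):
            alt = fit_cmp(freq_design, start={"delta": ref.delta + shift})
            assert alt.loglik == pytest.approx(ref.loglik, abs=1e-6)
            np.testing.assert_allclose(alt.delta, ref.delta, atol=1e-5)

    def test_recovers_generating_parameters(self):
        y = cmp_sample(20_000, CMPParams(0.45, 1.6), seed=13)
        fit = fit_cmp(DesignSet.from_outcome(y))
        assert abs(fit.beta[0] - np.log(0.45)) < 3.0 * fit.se_beta[0]
        assert abs(fit.delta[0] - np.log(1.6)) < 3.0 * fit.se_delta[0]


class TestZip:
    def test_boundary_when_no_zero_inflation(self, fixture_fits):
        fit = fixture_fits["zip"]
        # underdispersed data carry no excess zeros: pi is driven to 0
        assert fit.boundary_flags["gamma"][0]
        assert fit.se_gamma[0] > 10.0
        assert fit.loglik == pytest.approx(fixture_fits["poisson"].loglik, abs=1e-4)

    def test_parameter_recovery(self):
        y = zicmp_sample(10_000, ZICMPParams(CMPParams(2.0, 1.0), 0.3), seed=14)
        fit = fit_zip(DesignSet.from_outcome(y))
        from scipy.special import expit

        pi_hat = expit(fit.gamma[0])
        pi_se = pi_hat * (1 - pi_hat) * fit.se_gamma[0]
        assert abs(pi_hat - 0.3) < 3.0 * pi_se
        assert abs(fit.beta[0] - np.log(2.0)) < 3.0 * fit.se_beta[0]

    def test_matches_statsmodels_zero_inflated_poisson(self):
        import statsmodels.api as sm

        y = zicmp_sample(4000, ZICMPParams(CMPParams(2.0, 1.0), 0.3), seed=15)
        design = DesignSet.from_outcome(y)
        ours = fit_zip(design)
        ref = sm.ZeroInflatedPoisson(y, np.ones((len(y), 1)), inflation="logit").fit(
            disp=False
        )
        # identical likelihood function: statsmodels orders (gamma, beta)
        theirs_at_ours = ref.model.loglike(np.array([ours.gamma[0], ours.beta[0]]))
        assert theirs_at_ours == pytest.approx(ours.loglik, abs=1e-8)
        # and our optimum is at least as good as theirs
        assert ours.loglik >= ref.llf - 1e-6

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_zip(DesignSet.from_outcome([0, 0, 0, 0]))


class TestZicmp:
    def test_reduces_to_cmp_without_zero_inflation(self):
        # With pi-truth 0 the finite-sample MLE of pi is either at the
        # boundary or a small interior value; either way the ZICMP fit adds
        # nothing significant over the CMP fit.
        from scipy.special import expit
        from scipy.stats import chi2

        y = cmp_sample(20_000, CMPParams(0.5, 1.5), seed=16)
        design = DesignSet.from_outcome(y)
        zi = fit_zicmp(design)
        cmp_fit = fit_cmp(design)
        assert zi.loglik >= cmp_fit.loglik - 1e-8
        lrt_stat = 2.0 * (zi.loglik - cmp_fit.loglik)
        assert lrt_stat < chi2.ppf(0.95, 1)
        assert zi.boundary_flags["gamma"][0] or expit(zi.gamma[0]) < 0.1

    def test_nesting_chain(self, fixture_fits):
        ll = {k: f.loglik for k, f in fixture_fits.items()}
        assert ll["zicmp"] >= max(ll["cmp"], ll["zip"]) - 1e-6
        assert max(ll["cmp"], ll["zip"]) >= ll["poisson"] - 1e-6

    def test_parameter_counts_and_aic(self, fixture_fits):
        expected_k = {"poisson": 1, "cmp": 2, "zip": 2, "zicmp": 3}
        for kind, fit in fixture_fits.items():
            assert fit.n_params == expected_k[kind]
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-10)


class TestFrequencyRecordEquivalence:
    @pytest.mark.parametrize("fitter", [fit_poisson, fit_cmp, fit_zip, fit_zicmp])
    def test_weighted_table_equals_expanded_records(self, freq, fitter):
        table_fit = fitter(DesignSet.from_frequency(freq))
        record_fit = fitter(DesignSet.from_outcome(freq.expand()))
        assert table_fit.loglik == pytest.approx(record_fit.loglik, abs=1e-8)
        np.testing.assert_allclose(table_fit.beta, record_fit.beta, atol=1e-8)


class TestPredictMean:
    def test_poisson_intercept_only(self, freq, fixture_fits, freq_design):
        mu = predict_mean(fixture_fits["poisson"], freq_design)
        np.testing.assert_allclose(mu, freq.mean, atol=1e-10)

    def test_zicmp_moment_match(self, freq, fixture_fits, freq_design):
        mu = predict_mean(fixture_fits["zicmp"], freq_design)
        weights = freq.counts / freq.n
        assert float(np.dot(weights, mu)) == pytest.approx(freq.mean, abs=1e-3)

    def test_structural_zero_rows_have_zero_mean(self, freq_design):
        fit = fit_zicmp(freq_design)
        forced = fit
        forced.gamma = np.array([30.0])  # pi -> 1
        mu = predict_mean(forced, freq_design)
        assert np.all(mu < 1e-10)

    def test_dimension_mismatch(self, fixture_fits):
        rec = pd.DataFrame({"fatalities": [0, 1], "month": ["January", "April"]})
        wide = build_design(rec, count_terms=("month",))
        with pytest.raises(ValueError, match="does not match"):
            predict_mean(fixture_fits["poisson"], wide)


def test_mle_beats_truth_loglik_at_weakly_identified_truths():
    """Closure property: the fitted ZICMP likelihood is never below the
    generating parameters' likelihood, replicate by replicate, even in the
    weakly identified small-rate regime."""
    from cmpreg.simulate import TrueCoefficients, generate_covariates, generate_deaths

    truths = TrueCoefficients(
        beta=np.array([-1.1]), delta=np.array([0.44]), gamma=np.array([-1.0])
    )
    for child in np.random.SeedSequence(99).spawn(5):
        rng = np.random.default_rng(child)
        rec = generate_covariates(5000, seed=rng)
        y = generate_deaths(rec, truths, seed=rng)
        design = DesignSet.from_outcome(y)
        fit = fit_zicmp(design)
        objective, _ = _make_objective(design, True, True, DEFAULT_CONTROL)
        loglik_truth = -objective(np.array([-1.1, 0.44, -1.0]))[0]
        assert fit.loglik >= loglik_truth - 1e-6
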