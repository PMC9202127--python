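"""Count-family distributions and maximum-likelihood fitting."""

import numpy as np
import pytest
import statsmodels.api as sm

from countsel import (
    CohortTable,
    CoefficientVector,
    FamilySpec,
    RankError,
    fit_mle,
    log_likelihood,
    log_pmf,
    mean_variance,
)
from conftest import make_count_table


class TestLogPmf:
    def test_poisson_zero_at_unit_mean(self):
        assert log_pmf(0, 1.0, FamilySpec("poisson")) == pytest.approx(-1.0)

    def test_zip_with_zero_inflation_off_reduces_to_poisson(self):
        zip_spec = FamilySpec("zip", phi=0.0)
        pois = FamilySpec("poisson")
        y = np.arange(21)
        np.testing.assert_allclose(
            log_pmf(y, 2.0, zip_spec), log_pmf(y, 2.0, pois), rtol=1e-12
        )

    def test_negbin_normalizes(self):
        spec = FamilySpec("negbin", theta=0.99)
        total = np.exp(log_pmf(np.arange(501), 1.21, spec)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize(
        "spec",
        [
            FamilySpec("poisson"),
            FamilySpec("negbin", theta=0.5),
            FamilySpec("negbin", theta=5.0),
            FamilySpec("zip", phi=0.3),
            FamilySpec("zinb", theta=1.2, phi=0.4),
        ],
        ids=lambda s: s.family,
    )
    @pytest.mark.parametrize("mu", [0.2, 1.0, 4.0])
    def test_pmf_normalization_grid(self, spec, mu):
        total = np.exp(log_pmf(np.arange(3000), mu, spec)).sum()
        assert total >= 1.0 - 1e-8
        assert total <= 1.0 + 1e-8

    @pytest.mark.parametrize("phi", [0.1, 0.5, 0.9])
    def test_zero_inflated_zero_mass_identity(self, phi):
        base = FamilySpec("negbin", theta=1.5)
        zi = FamilySpec("zinb", theta=1.5, phi=phi)
        expected = phi + (1 - phi) * np.exp(log_pmf(0, 2.3, base))
        assert np.exp(log_pmf(0, 2.3, zi)) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            log_pmf(-1, 1.0, FamilySpec("poisson"))
        with pytest.raises(ValueError):
            log_pmf(1.5, 1.0, FamilySpec("poisson"))
        with pytest.raises(ValueError):
            log_pmf(1, 0.0, FamilySpec("poisson"))


class TestMeanVariance:
    def test_poisson_equidispersion(self):
        assert mean_variance(FamilySpec("poisson"), 3.0) == (3.0, 3.0)

    def test_negbin_overdispersion(self):
        m, v = mean_variance(FamilySpec("negbin", theta=1.0), 2.0)
        assert (m, v) == (2.0, 6.0)

    def test_negbin_poisson_limit(self):
        _, v = mean_variance(FamilySpec("negbin", theta=1e9), 2.0)
        assert v == pytest.approx(2.0, rel=1e-6)


class TestLogLikelihood:
    def test_single_zero_intercept_only_poisson(self):
        tab = CohortTable(np.zeros((1, 0)), np.array([0]), [])
        coef = CoefficientVector(0.0, np.zeros(0))
        assert log_likelihood(tab, coef, FamilySpec("poisson")) == pytest.approx(-1.0)

    def test_additivity_over_disjoint_subsets(self, negbin_table):
        spec = FamilySpec("negbin", theta=1.3)
        coef = CoefficientVector(0.2, np.array([0.4, -0.3, 0.1, 0.0, 0.0]))
        half = negbin_table.n // 2
        rows = np.arange(negbin_table.n)
        full = log_likelihood(negbin_table, coef, spec)
        part = log_likelihood(negbin_table.subset(rows < half), coef, spec) + \
            log_likelihood(negbin_table.subset(rows >= half), coef, spec)
        assert full == pytest.approx(part, rel=1e-12)

    def test_mle_dominates_perturbed_coefficients(self, poisson_table):
        spec = FamilySpec("poisson")
        fit = fit_mle(poisson_table, spec)
        best = fit.loglik
        rng = np.random.default_rng(0)
        for _ in range(20):
            coef = CoefficientVector(
                fit.coefficients.intercept + rng.normal(scale=0.1),
                fit.coefficients.slopes + rng.normal(scale=0.1, size=poisson_table.p),
            )
            assert log_likelihood(poisson_table, coef, spec) <= best + 1e-9


class TestFitMle:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(2.5, size=200)
        tab = CohortTable(np.zeros((200, 0)), y, [])
        fit = fit_mle(tab, FamilySpec("poisson"))
        assert fit.coefficients.intercept == pytest.approx(np.log(y.mean()), abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_poisson_agrees_with_irls_oracle(self, seed):
        tab = make_count_table(100 + seed, n=150, p=3, beta=[0.4, -0.3])
        fit = fit_mle(tab, FamilySpec("poisson"))
        oracle = sm.GLM(tab.y, sm.add_constant(tab.X),
                        family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.estimates(), oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, oracle.bse, atol=1e-5)

    def test_negbin_huge_theta_matches_poisson(self, poisson_table):
        f_nb = fit_mle(poisson_table, FamilySpec("negbin", theta=1e6))
        f_po = fit_mle(poisson_table, FamilySpec("poisson"))
        np.testing.assert_allclose(f_nb.estimates(), f_po.estimates(), atol=1e-3)

    def test_negbin_parameter_recovery(self):
        true = np.array([0.6, -0.5, 0.4, 0.0, 0.0])
        tab = make_count_table(42, n=2000, p=5, beta=true[:3], theta=1.0)
        fit = fit_mle(tab, FamilySpec("negbin"))
        est = fit.coefficients.slopes
        assert np.all(np.abs(est - true) < 3 * fit.se[1:])
        assert abs(fit.theta - 1.0) < 0.2

    def test_wald_z_is_estimate_over_se(self, negbin_table):
        fit = fit_mle(negbin_table, FamilySpec("negbin"))
        np.testing.assert_allclose(fit.z, fit.estimates() / fit.se, rtol=1e-12)

    def test_singular_design_raises_rank_error(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x])
        tab = CohortTable(X, rng.poisson(1.0, 50), ["a", "b"])
        with pytest.raises(RankError):
            fit_mle(tab, FamilySpec("poisson"))

    def test_zip_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        n = 400
        X = rng.standard_normal((n, 3))
        mu = np.exp(0.3 + X @ np.array([0.5, -0.4, 0.0]))
        y = np.where(rng.random(n) < 0.3, 0, rng.poisson(mu))
        tab = CohortTable(X, y, ["a", "b", "c"])
        fit = fit_mle(tab, FamilySpec("zip", phi_model="intercept"))
        oracle = sm.ZeroInflatedPoisson(
            y, sm.add_constant(X), exog_infl=np.ones((n, 1))
        ).fit(disp=0)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-3)
        np.testing.assert_allclose(fit.estimates(), oracle.params[1:], atol=1e-3)

    def test_aic_bic_definitions(self, negbin_table):
        fit = fit_mle(negbin_table, FamilySpec("negbin"))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + np.log(negbin_table.n) * fit.n_params
        )
        footer_terms = fit.summary_frame()["term"].tolist()
        for t in ("theta", "AIC", "BIC", "Log-likelihood"):
            assert t in footer_terms
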