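"""Penalized path solver, lambda tuning, and downstream refitting."""

import numpy as np
import pytest

from countsel import (
    CohortTable,
    CVSpec,
    FamilySpec,
    LambdaPath,
    PenaltySpec,
    cross_validate,
    fit_mle,
    fit_penalized,
    kkt_violations,
    log_likelihood,
    make_lambda_path,
    refit_unpenalized,
    select_support,
)
from countsel.penalized_fit import _standardize, _working
from conftest import make_count_table


@pytest.fixture(scope="module")
def nb_table():
    return make_count_table(21, n=250, p=8, beta=[0.6, -0.5, 0.4], theta=1.0)


class TestLambdaPath:
    def test_all_slopes_zero_at_lambda_max(self, nb_table):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                            n_lambda=30)
        assert np.all(fit.slopes_std[0] == 0.0)
        # intercept equals the intercept-only MLE
        null = fit_mle(CohortTable(np.zeros((nb_table.n, 0)), nb_table.y, []),
                       FamilySpec("negbin"))
        assert fit.intercepts[0] == pytest.approx(null.coefficients.intercept, abs=1e-6)

    def test_n_lambda_one_returns_lambda_max_only(self, nb_table):
        path = make_lambda_path(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                                n_lambda=1)
        assert path.n_lambda == 1
        assert path.lambda_max == path.grid[0]

    def test_constant_response_rejected(self):
        tab = CohortTable(np.random.default_rng(0).standard_normal((50, 3)),
                          np.ones(50, dtype=int), ["a", "b", "c"])
        with pytest.raises(ValueError, match="degenerate"):
            make_lambda_path(tab, FamilySpec("poisson"), PenaltySpec("lasso"))

    def test_grid_must_decrease(self):
        with pytest.raises(ValueError):
            LambdaPath([0.1, 0.2])


class TestFitPenalized:
    def test_lambda_zero_matches_mle(self):
        tab = make_count_table(31, n=200, p=4, beta=[0.5, -0.4], theta=1.0)
        spec = FamilySpec("negbin")
        pen = PenaltySpec("mcp")
        base = make_lambda_path(tab, spec, pen, n_lambda=20)
        path = LambdaPath(np.append(base.grid, 0.0))
        fit = fit_penalized(tab, spec, pen, path=path)
        mle = fit_mle(tab, spec)
        np.testing.assert_allclose(fit.slopes[-1], mle.coefficients.slopes, atol=1e-4)
        assert fit.intercepts[-1] == pytest.approx(mle.coefficients.intercept, abs=1e-4)

    def test_orthogonal_design_lasso_is_soft_threshold(self):
        # on an orthogonalized design every slope must equal the
        # soft-thresholded univariate working estimate at convergence
        rng = np.random.default_rng(8)
        raw = rng.standard_normal((400, 4))
        q, _ = np.linalg.qr(raw)
        X = q * np.sqrt(400)  # orthonormal columns scaled to unit variance
        mu = np.exp(0.2 + X @ np.array([0.5, -0.3, 0.0, 0.0]))
        tab = CohortTable(X, rng.poisson(mu), ["a", "b", "c", "d"])
        spec, pen = FamilySpec("poisson"), PenaltySpec("lasso")
        fit = fit_penalized(tab, spec, pen, n_lambda=20)
        i = 10
        lam = fit.lambdas[i]
        Xs, _, _ = _standardize(tab.X)
        beta = fit.slopes_std[i]
        b0 = fit.intercepts[i] + beta @ (fit.center / fit.scale)
        eta = b0 + Xs @ beta
        mu_hat = np.exp(eta)
        w, z = _working(tab.y.astype(float), eta, mu_hat, "poisson", None)
        n = tab.n
        for j in range(tab.p):
            vj = np.sum(w * Xs[:, j] ** 2) / n
            zj = np.sum(w * Xs[:, j] * (z - eta)) / n + vj * beta[j]
            soft = np.sign(zj) * max(abs(zj) - lam, 0.0) / vj
            assert beta[j] == pytest.approx(soft, abs=1e-4)

    def test_covariate_rescaling_leaves_support_unchanged(self, nb_table):
        spec, pen = FamilySpec("negbin"), PenaltySpec("mcp")
        fit1 = fit_penalized(nb_table, spec, pen, n_lambda=25)
        scaled = CohortTable(nb_table.X * 2.0, nb_table.y, list(nb_table.columns))
        fit2 = fit_penalized(scaled, spec, pen, n_lambda=25)
        np.testing.assert_array_equal(fit1.slopes_std != 0, fit2.slopes_std != 0)

    @pytest.mark.parametrize("kind", ["lasso", "alasso", "scad", "mcp"])
    def test_kkt_stationarity_at_convergence(self, nb_table, kind):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec(kind),
                            n_lambda=25)
        for i in [0, 8, 16, 24]:
            zero_v, nonzero_v = kkt_violations(fit, nb_table, fit.lambdas[i])
            assert zero_v <= 1e-4
            assert nonzero_v <= 1e-4

    def test_poisson_equals_negbin_with_huge_theta(self):
        tab = make_count_table(33, n=200, p=5, beta=[0.5, -0.4])
        pen = PenaltySpec("lasso")
        fp = fit_penalized(tab, FamilySpec("poisson"), pen, n_lambda=15)
        fn = fit_penalized(tab, FamilySpec("negbin", theta=1e6), pen,
                           path=LambdaPath(fp.lambdas))
        np.testing.assert_allclose(fp.slopes, fn.slopes, atol=1e-3)

    def test_warm_start_path_continuity(self, nb_table):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                            n_lambda=60)
        jumps = np.abs(np.diff(fit.slopes_std, axis=0)).max(axis=1)
        assert np.all(jumps < 0.35)

    def test_theta_profiled_along_path(self, nb_table):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                            n_lambda=10)
        assert fit.thetas is not None
        assert np.all(fit.thetas > 0)
        # adding signal covariates should not decrease the fitted theta
        assert fit.thetas[-1] >= fit.thetas[0] * 0.5


class TestCrossValidate:
    def test_loss_curve_shape_and_determinism(self, nb_table):
        spec, pen = FamilySpec("negbin"), PenaltySpec("mcp")
        res1 = cross_validate(nb_table, spec, pen, cv=CVSpec(folds=5, seed=3),
                              n_lambda=20)
        res2 = cross_validate(nb_table, spec, pen, cv=CVSpec(folds=5, seed=3),
                              n_lambda=20)
        assert res1.mean_loss.shape == (20,)
        assert res1.selected_lambda == res2.selected_lambda
        np.testing.assert_array_equal(res1.mean_loss, res2.mean_loss)

    def test_pure_noise_selects_near_empty_support(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((400, 10))
        y = rng.poisson(1.0, 400)
        tab = CohortTable(X, y, [f"x{i}" for i in range(10)])
        res = cross_validate(tab, FamilySpec("poisson"), PenaltySpec("mcp"),
                             cv=CVSpec(folds=10, seed=1), n_lambda=30)
        assert select_support(res.fit).n_selected <= 2
        assert res.selected_lambda >= res.lambdas[-1]

    def test_informative_support_recovered(self):
        tab = make_count_table(55, n=500, p=10, beta=[0.8, -0.8, 0.6, -0.6, 0.5],
                               intercept=0.5, theta=1.0)
        res = cross_validate(tab, FamilySpec("negbin"), PenaltySpec("mcp"),
                             cv=CVSpec(folds=10, seed=2), n_lambda=50)
        sel = set(select_support(res.fit).selected)
        assert {"x1", "x2", "x3", "x4", "x5"} <= sel


class TestSelectionAndRefit:
    def test_empty_support_at_lambda_max(self, nb_table):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                            n_lambda=10)
        sel = select_support(fit, lam=fit.lambdas[0])
        assert sel.selected == []

    def test_support_size_equals_df(self, nb_table):
        fit = fit_penalized(nb_table, FamilySpec("negbin"), PenaltySpec("mcp"),
                            n_lambda=20)
        for i in range(fit.n_lambda):
            assert select_support(fit, lam=fit.lambdas[i]).n_selected == fit.df[i]

    def test_full_support_refit_equals_full_mle(self, nb_table):
        spec = FamilySpec("negbin")
        refit = refit_unpenalized(nb_table, list(nb_table.columns), spec=spec)
        full = fit_mle(nb_table, spec)
        np.testing.assert_allclose(refit.estimates(), full.estimates(), atol=1e-8)

    def test_refit_improves_on_penalized_loglik(self, nb_table):
        spec = FamilySpec("negbin")
        res = cross_validate(nb_table, spec, PenaltySpec("mcp"),
                             cv=CVSpec(folds=5, seed=9), n_lambda=25)
        sel = select_support(res.fit)
        if not sel.selected:
            pytest.skip("empty support on this draw")
        refit = refit_unpenalized(nb_table, sel, spec=spec)
        sub = nb_table.select_columns(sel.selected)
        pen_ll = log_likelihood(sub, _restrict(res.fit, sel.selected),
                                res.fit.family_at())
        assert refit.loglik >= pen_ll - 1e-6

    def test_empty_refit_rejected(self, nb_table):
        with pytest.raises(ValueError):
            refit_unpenalized(nb_table, [])


def _restrict(fit, cols):
    from countsel import CoefficientVector

    coef = fit.coefficients()
    idx = [fit.columns.index(c) for c in cols]
    return CoefficientVector(coef.intercept, coef.slopes[idx])
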