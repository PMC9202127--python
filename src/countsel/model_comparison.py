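"""Non-nested model comparison: the Vuong test and nested-CV RMSE.

The Vuong statistic compares two fitted models pointwise: with
``m_i = log f1(y_i) - log f2(y_i)``,

    z = sqrt(n) * mbar_corrected / sd(m),    p = 1 - Phi(z)   (one-sided),

where the BIC correction subtracts ``(k1 - k2) * log(n) / (2n)`` from the
mean of m (the AIC correction subtracts ``(k1 - k2)/n``).  Positive z favors
model 1.  For penalized fits the parameter count k is the number of nonzero
coefficients plus the intercept plus theta where estimated.

``nested_cv_rmse`` compares NB-MCP and the random forest on prediction:
each outer fold tunes inside its training portion only (lambda by inner CV;
the forest's mtry by OOB error) and is scored by root-mean-squared error on
the outer test portion; a paired two-sided t-test summarizes the
fold-by-fold differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .alt_selectors import ForestParams, fit_forest
from .families import (
    CohortTable,
    CoefficientVector,
    FamilySpec,
    FitResult,
    pointwise_log_likelihood,
)
from .penalized_fit import CVSpec, PenalizedFit, PenaltySpec, cross_validate

__all__ = [
    "VuongResult",
    "RmseComparison",
    "vuong_test",
    "vuong_table",
    "nested_cv_rmse",
    "DegenerateVuongError",
    "model_pointwise_loglik",
    "model_k",
]


class DegenerateVuongError(ValueError):
    """Both models have identical pointwise likelihoods; z is undefined."""


@dataclass
class VuongResult:
    z: float
    p_value: float
    correction: str
    n: int
    mean_diff: float
    sd_diff: float

    @property
    def favors(self) -> int:
        """+1 if model 1 fits better pointwise, -1 if model 2."""
        return 1 if self.z > 0 else -1


@dataclass
class RmseComparison:
    method_names: tuple[str, str]
    rmse_1: np.ndarray  # per outer fold
    rmse_2: np.ndarray
    p_value: float

    def summary(self) -> dict:
        return {
            self.method_names[0]: {
                "mean": float(np.mean(self.rmse_1)),
                "sd": float(np.std(self.rmse_1, ddof=1)),
            },
            self.method_names[1]: {
                "mean": float(np.mean(self.rmse_2)),
                "sd": float(np.std(self.rmse_2, ddof=1)),
            },
            "paired_p_value": self.p_value,
        }


def model_pointwise_loglik(model, data: CohortTable) -> np.ndarray:
    """Per-subject log-likelihood for a FitResult or a selected PenalizedFit."""
    if isinstance(model, FitResult):
        sub = data.select_columns([c for c in model.names if c != "(Intercept)"])
        return pointwise_log_likelihood(sub, model.coefficients, model.family)
    if isinstance(model, PenalizedFit):
        coef = model.coefficients()
        fam = model.family_at()
        sub = data.select_columns(model.columns)
        return pointwise_log_likelihood(sub, coef, fam)
    raise TypeError(f"unsupported model type {type(model)!r}")


def model_k(model) -> int:
    """Free-parameter count: nonzero coefficients + intercept (+ theta, + zero part)."""
    if isinstance(model, FitResult):
        return model.n_params
    if isinstance(model, PenalizedFit):
        i = model.lambda_index()
        k = 1 + int(np.count_nonzero(model.slopes_std[i]))
        if model.thetas is not None:
            k += 1
        if model.zero_parts is not None:
            k += 1 + int(np.count_nonzero(model.zero_parts[i, 1:]))
        return k
    raise TypeError(f"unsupported model type {type(model)!r}")


def vuong_test(model1, model2, data: CohortTable, correction: str = "bic") -> VuongResult:
    """One-sided Vuong test of model 1 against model 2 on the same subjects.

    The caller is responsible for the models being non-nested (the statistic
    is computed regardless).  ``correction`` is one of ``none``, ``aic``,
    ``bic``.
    """
    if correction not in ("none", "aic", "bic"):
        raise ValueError("correction must be 'none', 'aic' or 'bic'")
    m = model_pointwise_loglik(model1, data) - model_pointwise_loglik(model2, data)
    n = data.n
    sd = float(np.std(m, ddof=1))
    if sd == 0.0:
        raise DegenerateVuongError("identical pointwise likelihoods; Vuong z undefined")
    dk = model_k(model1) - model_k(model2)
    mbar = float(np.mean(m))
    if correction == "bic":
        mbar -= dk * np.log(n) / (2.0 * n)
    elif correction == "aic":
        mbar -= dk / n
    z = float(np.sqrt(n) * mbar / sd)
    return VuongResult(
        z=z, p_value=float(stats.norm.sf(z)), correction=correction, n=n,
        mean_diff=mbar, sd_diff=sd,
    )


def vuong_table(reference, comparators: dict[str, object], data: CohortTable,
                correction: str = "bic"):
    """Table of Vuong comparisons of one reference model against several
    alternatives; non-convergent comparators appear with blank statistics."""
    import pandas as pd

    rows = []
    for name, model in comparators.items():
        if isinstance(model, PenalizedFit):
            ok = bool(model.converged[model.lambda_index()])
        else:
            ok = model is not None and bool(getattr(model, "converged", True))
        if not ok:
            rows.append({"comparator": name, "z": np.nan, "p_value": np.nan,
                         "better_fit": "not converged"})
            continue
        try:
            res = vuong_test(reference, model, data, correction)
        except DegenerateVuongError:
            rows.append({"comparator": name, "z": np.nan, "p_value": np.nan,
                         "better_fit": "degenerate"})
            continue
        rows.append({
            "comparator": name, "z": res.z, "p_value": res.p_value,
            "better_fit": "reference" if res.z > 0 else name,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nested cross-validation RMSE
# ---------------------------------------------------------------------------


def _tune_forest_oob(train: CohortTable, seed: int, n_trees: int) -> ForestParams:
    p = train.p
    grid = sorted({max(1, p // 6), max(1, int(np.ceil(p / 3))), max(1, p // 2)})
    best, best_err = None, np.inf
    for mtry in grid:
        params = ForestParams(n_trees=n_trees, mtry=mtry, seed=seed)
        fit = fit_forest(train, params)
        if fit.oob_mse < best_err:
            best, best_err = params, fit.oob_mse
    return best


def nested_cv_rmse(
    data: CohortTable,
    outer_folds: int = 5,
    inner_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    n_trees: int = 500,
    penalty: str = "mcp",
) -> RmseComparison:
    """NB-penalized vs random-forest predictive RMSE via nested CV.

    Outer folds partition the subjects; inner tuning (lambda by CV, mtry by
    OOB) sees only the outer-training rows.  Both methods are scored on
    identical outer-test portions; folds where either method fails are
    dropped pairwise.
    """
    rng = np.random.default_rng(seed)
    labels = np.resize(np.arange(outer_folds), data.n)[rng.permutation(data.n)]
    rmse_nb, rmse_rf = [], []
    for k in range(outer_folds):
        train = data.subset(labels != k)
        test = data.subset(labels == k)
        try:
            res = cross_validate(
                train, FamilySpec("negbin"), PenaltySpec(kind=penalty),
                cv=CVSpec(folds=inner_folds, seed=seed + 1000 + k),
                n_lambda=n_lambda,
            )
            mu = res.fit.predict_mu(test.X)
            params = _tune_forest_oob(train, seed + 2000 + k, n_trees)
            forest = fit_forest(train, params)
            pred_rf = forest.predict(test.X)
        except Exception:  # noqa: BLE001 - dropped pairwise, reported via count
            continue
        rmse_nb.append(float(np.sqrt(np.mean((test.y - mu) ** 2))))
        rmse_rf.append(float(np.sqrt(np.mean((test.y - pred_rf) ** 2))))
    rmse_nb = np.asarray(rmse_nb)
    rmse_rf = np.asarray(rmse_rf)
    diffs = rmse_nb - rmse_rf
    if rmse_nb.size < 2 or np.allclose(diffs, diffs[0]):
        p = 1.0 if np.allclose(diffs, 0.0) else np.nan
    else:
        p = float(stats.ttest_rel(rmse_nb, rmse_rf).pvalue)
    return RmseComparison((f"negbin-{penalty}", "rf"), rmse_nb, rmse_rf, p)
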