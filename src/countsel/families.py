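"""Count-data model families: Poisson, negative binomial, zero-inflated mixtures.

The negative binomial (NB) is parameterized by its mean ``mu`` and shape
``theta`` (the ``k`` of the classical NB2 form), so that

    E[Y] = mu,    Var[Y] = mu + mu**2 / theta.

``theta -> inf`` recovers the Poisson.  Note that some software reports the
reciprocal ``alpha = 1/theta`` instead; everything here uses ``theta``.

Zero-inflated (ZI) families mix a degenerate point mass at zero (mixing
proportion ``phi``) with a base Poisson or NB count component:

    P(Y=0) = phi + (1-phi) * P_base(0)
    P(Y=y) = (1-phi) * P_base(y),  y >= 1.

Unpenalized maximum likelihood uses iteratively reweighted least squares
(IRLS) with a log link; for the NB, ``theta`` is profiled by alternating a
``theta`` maximization with the IRLS beta step.  ZI families are fit by EM
with structural-zero responsibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CohortTable",
    "FamilySpec",
    "CoefficientVector",
    "FitResult",
    "log_pmf",
    "mean_variance",
    "log_likelihood",
    "fit_mle",
    "RankError",
]

# Convergence conventions shared by the unpenalized and penalized solvers.
LOGLIK_RTOL = 1e-8
MAX_OUTER_ITER = 100
MAX_EM_ITER = 200
ETA_CLIP = 30.0  # linear predictors are clipped to +-30 before exp()

_COUNT_FAMILIES = ("poisson", "negbin", "zip", "zinb")


class RankError(ValueError):
    """Raised when a design matrix is not of full column rank."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Patient-level table: a count response plus a numeric design matrix.

    ``X`` holds dummy-encoded categoricals and quantitative covariates; the
    response is a nonnegative integer count (e.g. number of
    rehospitalizations).  After imputation no cell may be missing.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(self.y)
        if y.ndim != 1 or y.shape[0] != self.X.shape[0]:
            raise ValueError("y must be 1-dimensional and conformable with X")
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("response must contain nonnegative integers")
        self.y = np.round(y).astype(np.int64)
        if self.n < 1:
            raise ValueError("need at least one subject")
        self.columns = list(self.columns)
        if len(self.columns) != self.p:
            raise ValueError("column names must match the number of covariates")
        if len(set(self.columns)) != self.p:
            raise ValueError("column names must be unique")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing cells")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "CohortTable":
        return CohortTable(self.X[rows], self.y[rows], list(self.columns))

    def select_columns(self, names: Sequence[str]) -> "CohortTable":
        idx = [self.columns.index(c) for c in names]
        return CohortTable(self.X[:, idx], self.y, [self.columns[i] for i in idx])

    def to_frame(self, response: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df[response] = self.y
        return df

    def to_csv(self, path, response: str = "y") -> None:
        self.to_frame(response).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, response: str = "y") -> "CohortTable":
        cols = [c for c in df.columns if c != response]
        return cls(df[cols].to_numpy(float), df[response].to_numpy(), cols)

    @classmethod
    def from_csv(cls, path, response: str = "y") -> "CohortTable":
        return cls.from_frame(pd.read_csv(path), response)


@dataclass(frozen=True)
class FamilySpec:
    """Which count family, with its auxiliary parameters.

    ``theta`` is the NB shape (ignored for Poisson-based families); ``phi``
    is a fixed zero-inflation mixing proportion used when evaluating
    probability mass directly.  ``phi_model`` chooses the zero-component
    design used by the fitters: ``"intercept"`` or ``"covariates"`` (logit
    link on the same covariates as the count part).
    """

    family: str = "negbin"
    theta: Optional[float] = None
    phi: Optional[float] = None
    phi_model: str = "covariates"

    def __post_init__(self) -> None:
        if self.family not in _COUNT_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("negbin", "zinb") and self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.phi is not None and not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must lie in [0, 1)")
        if self.phi_model not in ("intercept", "covariates"):
            raise ValueError("phi_model must be 'intercept' or 'covariates'")

    @property
    def is_zero_inflated(self) -> bool:
        return self.family in ("zip", "zinb")

    @property
    def base_family(self) -> str:
        return {"zip": "poisson", "zinb": "negbin"}.get(self.family, self.family)


@dataclass
class CoefficientVector:
    """Regression coefficients on the log-mean scale (plus an optional
    zero-component block for zero-inflated families, logit scale)."""

    intercept: float
    slopes: np.ndarray
    zero_part: Optional[np.ndarray] = None  # [intercept, slopes...] on logit scale

    def __post_init__(self) -> None:
        self.slopes = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        if self.zero_part is not None:
            self.zero_part = np.asarray(self.zero_part, dtype=float)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.slopes

    def mu(self, X: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(self.linear_predictor(X), -ETA_CLIP, ETA_CLIP))

    def phi(self, X: np.ndarray) -> np.ndarray:
        """Per-subject zero-inflation probability (zero vector design -> scalar)."""
        if self.zero_part is None:
            raise ValueError("no zero component")
        if self.zero_part.size == 1:
            eta = np.full(X.shape[0], self.zero_part[0])
        else:
            eta = self.zero_part[0] + X @ self.zero_part[1:]
        return special.expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))


@dataclass
class FitResult:
    """An unpenalized maximum-likelihood fit in reporting form."""

    coefficients: CoefficientVector
    names: list[str]
    loglik: float
    se: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    n_params: int
    n_obs: int
    family: FamilySpec
    theta: Optional[float] = None
    theta_se: Optional[float] = None
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params

    def estimates(self) -> np.ndarray:
        return np.concatenate([[self.coefficients.intercept], self.coefficients.slopes])

    def to_table(self) -> pd.DataFrame:
        """Regression table: estimate / SE / Wald z / two-sided p per term."""
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimates(),
                "se": self.se,
                "z": self.z,
                "p_value": self.p_value,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        """Full report: the coefficient table plus theta / AIC / BIC / loglik rows."""
        tab = self.to_table()
        extra = [("AIC", self.aic), ("BIC", self.bic), ("Log-likelihood", self.loglik)]
        if self.theta is not None:
            extra.insert(0, ("theta", self.theta))
        footer = pd.DataFrame(
            {"term": [k for k, _ in extra], "estimate": [v for _, v in extra]}
        )
        return pd.concat([tab, footer], ignore_index=True)

    def to_json_dict(self) -> dict:
        d = {
            "family": self.family.family,
            "terms": self.names,
            "estimate": self.estimates().tolist(),
            "se": np.asarray(self.se).tolist(),
            "z": np.asarray(self.z).tolist(),
            "p_value": np.asarray(self.p_value).tolist(),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
        }
        if self.theta is not None:
            d["theta"] = float(self.theta)
            d["theta_se"] = None if self.theta_se is None else float(self.theta_se)
        if self.coefficients.zero_part is not None:
            d["zero_part"] = self.coefficients.zero_part.tolist()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "FitResult":
        est = np.asarray(d["estimate"], dtype=float)
        zero = np.asarray(d["zero_part"], dtype=float) if "zero_part" in d else None
        theta = d.get("theta")
        return cls(
            coefficients=CoefficientVector(est[0], est[1:], zero_part=zero),
            names=list(d["terms"]),
            loglik=float(d["loglik"]),
            se=np.asarray(d["se"], dtype=float),
            z=np.asarray(d["z"], dtype=float),
            p_value=np.asarray(d["p_value"], dtype=float),
            n_params=int(d["n_params"]),
            n_obs=int(d["n_obs"]),
            family=FamilySpec(d["family"], theta=theta),
            theta=theta,
            theta_se=d.get("theta_se"),
            converged=bool(d.get("converged", True)),
        )


# ---------------------------------------------------------------------------
# Probability mass
# ---------------------------------------------------------------------------


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    return np.round(y).astype(np.int64)


def _base_log_pmf(y: np.ndarray, mu: np.ndarray, family: str, theta: Optional[float]) -> np.ndarray:
    if family == "poisson":
        return y * np.log(mu) - mu - special.gammaln(y + 1.0)
    if family == "negbin":
        if theta is None or theta <= 0:
            raise ValueError("negbin requires theta > 0")
        k = theta
        return (
            special.gammaln(y + k)
            - special.gammaln(k)
            - special.gammaln(y + 1.0)
            + y * (np.log(mu) - np.log(mu + k))
            + k * (np.log(k) - np.log(mu + k))
        )
    raise ValueError(family)


def log_pmf(y, mu, spec: FamilySpec) -> np.ndarray | float:
    """Log probability mass of ``y`` under ``spec`` with mean parameter ``mu``.

    For zero-inflated families the two-branch mixture is evaluated exactly:
    mass ``phi + (1-phi) * P_base(0)`` at zero and ``(1-phi) * P_base(y)``
    elsewhere, with ``phi`` taken from ``spec.phi`` (0 if unset).
    """
    scalar = np.isscalar(y) and np.isscalar(mu)
    y = _check_counts(np.atleast_1d(y))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    y, mu = np.broadcast_arrays(y, mu)
    base = _base_log_pmf(y, mu, spec.base_family, spec.theta)
    if spec.is_zero_inflated:
        phi = 0.0 if spec.phi is None else spec.phi
        out = np.log1p(-phi) + base
        at_zero = y == 0
        if np.any(at_zero):
            out = np.where(
                at_zero,
                np.logaddexp(np.log(phi) if phi > 0 else -np.inf, np.log1p(-phi) + base),
                out,
            )
        base = out
    return float(base[0]) if scalar else base


def mean_variance(spec: FamilySpec, mu: float) -> tuple[float, float]:
    """Mean and variance of the count distribution at mean parameter ``mu``.

    Poisson is equidispersed; NB has ``Var = mu + mu**2/theta``.  For
    zero-inflated families the moments are of the mixture (base moments
    deflated by ``1-phi``).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    base = spec.base_family
    if base == "poisson":
        m, v = mu, mu
    else:
        if spec.theta is None or spec.theta <= 0:
            raise ValueError("negbin requires theta > 0")
        m, v = mu, mu + mu**2 / spec.theta
    if spec.is_zero_inflated:
        phi = 0.0 if spec.phi is None else spec.phi
        mean = (1 - phi) * m
        var = (1 - phi) * (v + m**2) - mean**2
        return mean, var
    return m, v


def pointwise_log_likelihood(
    data: CohortTable, coef: CoefficientVector, spec: FamilySpec
) -> np.ndarray:
    """Per-subject log-likelihood contributions (used by the Vuong test)."""
    mu = coef.mu(data.X)
    if spec.is_zero_inflated and coef.zero_part is not None:
        phi = coef.phi(data.X)
        base = _base_log_pmf(data.y, mu, spec.base_family, spec.theta)
        out = np.log1p(-phi) + base
        at_zero = data.y == 0
        with np.errstate(divide="ignore"):
            log_phi = np.where(phi > 0, np.log(np.maximum(phi, 1e-300)), -np.inf)
        out = np.where(at_zero, np.logaddexp(log_phi, np.log1p(-phi) + base), out)
        return out
    return np.asarray(log_pmf(data.y, mu, spec))


def log_likelihood(data: CohortTable, coef: CoefficientVector, spec: FamilySpec) -> float:
    """Total log-likelihood sum_i log f(y_i | mu_i) with mu_i = exp(b0 + x_i'b)."""
    return float(np.sum(pointwise_log_likelihood(data, coef, spec)))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _profile_theta(y: np.ndarray, mu: np.ndarray, weights: Optional[np.ndarray] = None,
                   theta0: float = 1.0) -> float:
    """Maximize the NB log-likelihood over theta at fixed means.

    Optimizes on the log scale over theta in [1e-3, 1e6]; weights support the
    fractional responsibilities of the zero-inflated EM.
    """
    w = np.ones_like(mu) if weights is None else weights

    def negll(log_theta: float) -> float:
        k = np.exp(log_theta)
        ll = (
            special.gammaln(y + k)
            - special.gammaln(k)
            + y * (np.log(mu) - np.log(mu + k))
            + k * (np.log(k) - np.log(mu + k))
        )
        return -float(np.sum(w * ll))

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(1e-3), np.log(1e6)), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def _irls_weights(y, mu, family, theta):
    """GLM working weights and response for a log link."""
    if family == "poisson":
        w = mu
    else:
        w = mu * theta / (mu + theta)
    z = np.log(mu) + (y - mu) / mu
    return w, z


def _wls_solve(Xd: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    wX = Xd * w[:, None]
    H = Xd.T @ wX
    try:
        return np.linalg.solve(H, wX.T @ z)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RankError("weighted least-squares system is singular") from exc


def _check_rank(Xd: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        # name the columns involved in the deficiency for the error message
        bad = []
        for j in range(1, Xd.shape[1]):
            sub = Xd[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(names[j])
        raise RankError(f"design is rank-deficient; aliased columns: {bad or names}")


def _fit_count_glm(
    data: CohortTable,
    family: str,
    theta: Optional[float],
    weights: Optional[np.ndarray] = None,
    estimate_theta: bool = True,
    y_float: Optional[np.ndarray] = None,
):
    """IRLS for Poisson / NB with optional prior weights and theta profiling.

    Returns (beta_full, theta, loglik_path_converged).  ``beta_full`` includes
    the intercept as its first entry.
    """
    Xd = np.column_stack([np.ones(data.n), data.X])
    y = data.y.astype(float) if y_float is None else y_float
    w_prior = np.ones(data.n) if weights is None else weights
    _check_rank(Xd, ["(Intercept)"] + list(data.columns))

    ybar = max(float(np.sum(w_prior * y) / np.sum(w_prior)), 1e-8)
    beta = np.zeros(Xd.shape[1])
    beta[0] = np.log(ybar)
    cur_theta = theta if theta is not None else 1.0
    last_obj = -np.inf
    converged = False
    for _ in range(MAX_OUTER_ITER):
        eta = np.clip(Xd @ beta, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        if family == "negbin" and estimate_theta:
            cur_theta = _profile_theta(y, mu, w_prior, cur_theta)
        w, z = _irls_weights(y, mu, family, cur_theta if family == "negbin" else None)
        beta = _wls_solve(Xd, w_prior * w, z)
        eta = np.clip(Xd @ beta, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        ll = _weighted_loglik(y, mu, family, cur_theta, w_prior)
        if np.isfinite(last_obj) and abs(ll - last_obj) <= LOGLIK_RTOL * (abs(last_obj) + 1.0):
            converged = True
            break
        last_obj = ll
    return beta, (cur_theta if family == "negbin" else None), converged


def _weighted_loglik(y, mu, family, theta, w):
    ll = _base_log_pmf(np.round(np.asarray(y)).astype(np.int64), mu, family, theta)
    # fractional y (EM M-step) needs the gamma form directly
    if not np.allclose(y, np.round(y)):
        if family == "poisson":
            ll = y * np.log(mu) - mu - special.gammaln(y + 1.0)
        else:
            ll = (
                special.gammaln(y + theta)
                - special.gammaln(theta)
                - special.gammaln(y + 1.0)
                + y * (np.log(mu) - np.log(mu + theta))
                + theta * (np.log(theta) - np.log(mu + theta))
            )
    return float(np.sum(w * ll))


def _fisher_information(Xd: np.ndarray, mu: np.ndarray, family: str, theta) -> np.ndarray:
    if family == "poisson":
        w = mu
    else:
        w = mu * theta / (mu + theta)
    return Xd.T @ (Xd * w[:, None])


def _logistic_irls(Xz: np.ndarray, target: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Weighted-logistic M-step: fit P(structural zero) to responsibilities."""
    gamma = np.zeros(Xz.shape[1])
    tbar = np.clip(target.mean(), 1e-6, 1 - 1e-6)
    gamma[0] = np.log(tbar / (1 - tbar))
    for _ in range(max_iter):
        eta = np.clip(Xz @ gamma, -ETA_CLIP, ETA_CLIP)
        p = special.expit(eta)
        w = np.maximum(p * (1 - p), 1e-8)
        z = eta + (target - p) / w
        new = _wls_solve(Xz, w, z)
        if np.max(np.abs(new - gamma)) < 1e-10:
            gamma = new
            break
        gamma = new
    return gamma


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate for the ZI observed information."""
    k = x0.size
    H = np.zeros((k, k))
    hs = eps * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def fit_mle(
    data: CohortTable,
    spec: FamilySpec,
    columns: Optional[Sequence[str]] = None,
) -> FitResult:
    """Unpenalized maximum-likelihood fit of a count regression model.

    Poisson and NB use IRLS with a log link; the NB shape ``theta`` is
    profiled by alternating theta- and beta-steps.  Standard errors come from
    the Fisher information at the optimum with ``theta`` held fixed (the
    usual NB-GLM convention).  Zero-inflated families are fit by EM, with
    standard errors from a finite-difference observed information of the full
    mixture log-likelihood.

    Non-convergence is reported through ``FitResult.converged``; a singular
    design raises :class:`RankError`.
    """
    if columns is not None:
        data = data.select_columns(columns)
    names = ["(Intercept)"] + list(data.columns)
    if spec.is_zero_inflated:
        return _fit_zero_inflated(data, spec, names)

    beta, theta, converged = _fit_count_glm(data, spec.family, spec.theta,
                                            estimate_theta=spec.theta is None)
    if spec.family == "negbin" and spec.theta is not None:
        theta = spec.theta
    Xd = np.column_stack([np.ones(data.n), data.X])
    mu = np.exp(np.clip(Xd @ beta, -ETA_CLIP, ETA_CLIP))
    info = _fisher_information(Xd, mu, spec.family, theta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))
    coef = CoefficientVector(beta[0], beta[1:])
    fitted_spec = replace(spec, theta=theta) if spec.family == "negbin" else spec
    ll = log_likelihood(data, coef, fitted_spec)

    theta_se = None
    if spec.family == "negbin" and spec.theta is None:
        # curvature of the profile log-likelihood in theta
        def pll(t):
            return _weighted_loglik(data.y.astype(float), mu, "negbin", t, np.ones(data.n))
        h = 1e-4 * theta
        d2 = (pll(theta + h) - 2 * pll(theta) + pll(theta - h)) / h**2
        if d2 < 0:
            theta_se = float(np.sqrt(-1.0 / d2))

    n_params = Xd.shape[1] + (1 if spec.family == "negbin" and spec.theta is None else 0)
    return FitResult(
        coefficients=coef, names=names, loglik=ll, se=se, z=zstat, p_value=pval,
        n_params=n_params, n_obs=data.n, family=fitted_spec, theta=theta,
        theta_se=theta_se, converged=converged,
    )


def _fit_zero_inflated(data: CohortTable, spec: FamilySpec, names: list[str]) -> FitResult:
    """EM for ZIP/ZINB: E-step structural-zero responsibilities, M-step a
    weighted count GLM plus a weighted logistic fit of the zero component."""
    base = spec.base_family
    y = data.y.astype(float)
    Xd = np.column_stack([np.ones(data.n), data.X])
    _check_rank(Xd, names)
    if spec.phi_model == "covariates":
        Xz = Xd
    else:
        Xz = np.ones((data.n, 1))

    at_zero = data.y == 0
    # initialize from a plain count fit and the empirical excess-zero share
    beta, theta, _ = _fit_count_glm(data, base, spec.theta, estimate_theta=spec.theta is None)
    r = np.where(at_zero, 0.5 * at_zero.mean(), 0.0)
    gamma = np.zeros(Xz.shape[1])
    gamma[0] = np.log(max(r.mean(), 1e-3) / (1 - max(r.mean(), 1e-3)))

    last_ll = -np.inf
    converged = False
    for _ in range(MAX_EM_ITER):
        mu = np.exp(np.clip(Xd @ beta, -ETA_CLIP, ETA_CLIP))
        phi = special.expit(np.clip(Xz @ gamma, -ETA_CLIP, ETA_CLIP))
        log_p0 = _base_log_pmf(np.zeros(data.n, dtype=np.int64), mu, base, theta)
        # E-step
        denom = phi + (1 - phi) * np.exp(log_p0)
        r = np.where(at_zero, phi / np.maximum(denom, 1e-300), 0.0)
        # M-step
        w_count = 1.0 - r
        beta, theta, _ = _fit_count_glm(
            data, base, spec.theta if spec.theta is not None else None,
            weights=np.maximum(w_count, 1e-10),
            estimate_theta=(base == "negbin" and spec.theta is None),
            y_float=y,
        )
        if base == "negbin" and spec.theta is not None:
            theta = spec.theta
        gamma = _logistic_irls(Xz, r)
        # observed-data log-likelihood
        coef = CoefficientVector(beta[0], beta[1:], zero_part=gamma)
        fam = replace(spec, theta=theta)
        ll = log_likelihood(data, coef, fam)
        if not np.isfinite(ll):
            break
        if np.isfinite(last_ll) and abs(ll - last_ll) <= LOGLIK_RTOL * (abs(last_ll) + 1.0):
            converged = True
            break
        last_ll = ll

    coef = CoefficientVector(beta[0], beta[1:], zero_part=gamma)
    fam = replace(spec, theta=theta)
    ll = log_likelihood(data, coef, fam)

    # SEs for the count part from finite-difference observed information of
    # the full mixture likelihood (theta and zero part held at the optimum)
    def negll_beta(b):
        c = CoefficientVector(b[0], b[1:], zero_part=gamma)
        return -log_likelihood(data, c, fam)

    k_beta = Xd.shape[1]
    try:
        H = _numerical_hessian(negll_beta, beta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k_beta, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))
    n_params = k_beta + Xz.shape[1] + (1 if base == "negbin" and spec.theta is None else 0)
    return FitResult(
        coefficients=coef, names=names, loglik=ll, se=se, z=zstat, p_value=pval,
        n_params=n_params, n_obs=data.n, family=fam,
        theta=theta if base == "negbin" else None, converged=converged,
    )
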