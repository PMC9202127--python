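"""Penalized count-regression solver.

Minimizes the penalized objective

    -(1/n) * loglik(b0, beta) + sum_j P_lambda(beta_j)

over a decreasing lambda path with warm starts.  The outer loop is IRLS: at
the current means it forms GLM working weights and responses (profiling the
NB shape ``theta`` each cycle); the inner loop is cyclic coordinate descent
whose univariate updates are the exact thresholding operators of
:mod:`countsel.penalties`.  Covariates are standardized to zero mean / unit
variance internally (penalties are scale-sensitive); the intercept, theta
and any zero-inflation parameters are never penalized; coefficients are
reported on the original scale.

Zero-inflated families wrap the same machinery in an EM loop: the E-step
assigns structural-zero responsibilities, the M-step runs a weighted
penalized count fit plus a penalized weighted-logistic fit of the zero
component (both slope sets share one lambda; intercepts unpenalized).

Lambda is tuned by k-fold cross-validation on held-out predictive deviance
(minimum mean loss; ties resolve to the larger, sparser lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import special

from .families import (
    ETA_CLIP,
    CohortTable,
    CoefficientVector,
    FamilySpec,
    FitResult,
    RankError,
    fit_mle,
    log_likelihood,
    pointwise_log_likelihood,
    _profile_theta,
)
from .penalties import (
    PENALTY_CODES,
    PenaltySpec,
    _threshold_scalar,
    adaptive_weights,
    penalty_total,
)

__all__ = [
    "LambdaPath",
    "PenalizedFit",
    "CVSpec",
    "CVResult",
    "SelectionResult",
    "make_lambda_path",
    "fit_penalized",
    "cross_validate",
    "select_support",
    "refit_unpenalized",
    "kkt_violations",
]

MAX_OUTER = 100
MAX_EM = 200
OBJ_RTOL = 1e-8
CD_TOL = 1e-7
CD_MAX_SWEEPS = 1000


@dataclass
class SelectionResult:
    """The outcome of a variable-selection procedure."""

    selected: list[str]
    method: str
    scores: Optional[dict[str, float]] = None  # p-value, minimal depth, ...

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def indices(self, columns: Sequence[str]) -> set[int]:
        return {list(columns).index(c) for c in self.selected}

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": list(self.selected),
            "n_selected": self.n_selected,
            "scores": self.scores,
        }


@dataclass
class LambdaPath:
    """A strictly decreasing penalty-strength grid starting at lambda_max."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.atleast_1d(np.asarray(self.grid, dtype=float))
        if np.any(self.grid < 0):
            raise ValueError("lambda values must be nonnegative")
        if np.any(np.diff(self.grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def n_lambda(self) -> int:
        return self.grid.size

    @property
    def lambda_max(self) -> float:
        return float(self.grid[0])


@dataclass
class CVSpec:
    """K-fold cross-validation settings for lambda tuning."""

    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")

    def assign(self, n: int) -> np.ndarray:
        """Fold label per subject; every subject is held out exactly once."""
        rng = np.random.default_rng(self.seed)
        labels = np.resize(np.arange(self.folds), n)
        return labels[rng.permutation(n)]


@dataclass
class PenalizedFit:
    """Solutions along the lambda path (original and standardized scale)."""

    lambdas: np.ndarray
    intercepts: np.ndarray            # (n_lambda,)
    slopes: np.ndarray                # (n_lambda, p) original scale
    slopes_std: np.ndarray            # (n_lambda, p) standardized scale
    df: np.ndarray                    # nonzero slopes per lambda
    loglik: np.ndarray
    thetas: Optional[np.ndarray]
    converged: np.ndarray
    columns: list[str]
    family: FamilySpec
    penalty: PenaltySpec
    center: np.ndarray
    scale: np.ndarray
    zero_parts: Optional[np.ndarray] = None  # ZI: (n_lambda, 1+p) logit scale
    selected_lambda: Optional[float] = None

    @property
    def n_lambda(self) -> int:
        return self.lambdas.size

    def lambda_index(self, lam: Optional[float] = None) -> int:
        if lam is None:
            if self.selected_lambda is None:
                raise ValueError("no lambda selected; run cross-validation first")
            lam = self.selected_lambda
        return int(np.argmin(np.abs(self.lambdas - lam)))

    def coefficients(self, lam: Optional[float] = None) -> CoefficientVector:
        i = self.lambda_index(lam)
        zp = None if self.zero_parts is None else self.zero_parts[i]
        return CoefficientVector(float(self.intercepts[i]), self.slopes[i], zero_part=zp)

    def family_at(self, lam: Optional[float] = None) -> FamilySpec:
        i = self.lambda_index(lam)
        if self.thetas is not None:
            return replace(self.family, theta=float(self.thetas[i]))
        return self.family

    def predict_mu(self, X: np.ndarray, lam: Optional[float] = None) -> np.ndarray:
        return self.coefficients(lam).mu(np.asarray(X, float))

    def path_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.slopes, columns=self.columns)
        df.insert(0, "lambda", self.lambdas)
        df.insert(1, "intercept", self.intercepts)
        df.insert(2, "df", self.df)
        df.insert(3, "loglik", self.loglik)
        if self.thetas is not None:
            df.insert(4, "theta", self.thetas)
        return df


@dataclass
class CVResult:
    """Cross-validation loss curve and the selected lambda."""

    lambdas: np.ndarray
    mean_loss: np.ndarray
    se_loss: np.ndarray
    selected_lambda: float
    fit: PenalizedFit  # full-data path fit with selected_lambda set
    fold_losses: np.ndarray  # (folds, n_lambda)
    skipped_folds: int = 0


# ---------------------------------------------------------------------------
# Standardization and working quantities
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale <= 0, 1.0, scale)
    return (X - center) / scale, center, scale


def _score_residual(y, mu, family: str, theta) -> np.ndarray:
    """d loglik_i / d eta_i for a log link."""
    if family == "poisson":
        return y - mu
    return (y - mu) * theta / (mu + theta)


def _working(y, eta, mu, family: str, theta):
    if family == "poisson":
        w = mu
    else:
        w = mu * theta / (mu + theta)
    z = eta + (y - mu) / mu
    return np.maximum(w, 1e-10), z


@njit(cache=False)
def _cd_sweeps(Xs, w, z, beta, b0, lam, code, a, pw, tol, max_sweeps):
    """Cyclic coordinate descent on the penalized weighted least-squares
    problem; updates ``beta`` in place and returns the new intercept."""
    n, p = Xs.shape
    v = np.zeros(p)
    # Proximal floor on the working curvature: when v_j <= 1/a (MCP) or
    # 1/(a-1) (SCAD) the univariate subproblem turns non-convex and exact
    # updates can jump arbitrarily far.  Raising the curvature is a valid
    # majorization step: fixed points (KKT stationarity) are unchanged,
    # only the step size shrinks.
    vfloor = 0.0
    if code == 1:
        vfloor = 1.05 / (a - 1.0)
    elif code == 2:
        vfloor = 1.05 / a
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * Xs[i, j] * Xs[i, j]
        vj = s / n
        v[j] = vj if vj > vfloor else vfloor
    r = np.empty(n)
    for i in range(n):
        s = b0
        for j in range(p):
            if beta[j] != 0.0:
                s += Xs[i, j] * beta[j]
        r[i] = z[i] - s
    sw = 0.0
    for i in range(n):
        sw += w[i]
    for _ in range(max_sweeps):
        maxd = 0.0
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / sw
        b0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > maxd:
            maxd = abs(d0)
        for j in range(p):
            if np.isinf(pw[j]) or v[j] <= 0.0:
                continue
            zj = 0.0
            for i in range(n):
                zj += w[i] * Xs[i, j] * r[i]
            zj = zj / n + v[j] * beta[j]
            bn = _threshold_scalar(zj, v[j], code, lam, a, pw[j])
            d = bn - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= Xs[i, j] * d
                beta[j] = bn
                if abs(d) > maxd:
                    maxd = abs(d)
        if maxd < tol:
            break
    return b0


def _penalized_objective(y, Xs, b0, beta, family, theta, pen: PenaltySpec,
                         weights=None) -> float:
    n = y.size
    eta = np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    from .families import _weighted_loglik

    w = np.ones(n) if weights is None else weights
    ll = _weighted_loglik(y, mu, family, theta, w)
    return -ll / n + penalty_total(beta, pen)


def _fit_one_lambda(y, Xs, family, pen: PenaltySpec, lam, b0, beta, theta,
                    estimate_theta, prior_weights=None, max_outer=MAX_OUTER):
    """IRLS + coordinate descent at a single lambda (standardized scale).

    ``beta`` is modified in place (warm start).  Returns
    (b0, theta, loglik, converged, monotone).
    """
    n = y.size
    code = PENALTY_CODES[pen.kind]
    pw = pen.weights if pen.weights is not None else np.ones(Xs.shape[1])
    pw = np.asarray(pw, dtype=float)
    wp = np.ones(n) if prior_weights is None else prior_weights
    yf = y.astype(float)

    spec_at = pen.with_lambda(lam)
    obj = _penalized_objective(yf, Xs, b0, beta, family, theta, spec_at, wp)
    converged = False
    monotone = True
    for _ in range(max_outer):
        eta = np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        if family == "negbin" and estimate_theta:
            theta = _profile_theta(yf, mu, wp, theta if theta else 1.0)
            obj = _penalized_objective(yf, Xs, b0, beta, family, theta, spec_at, wp)
        w, z = _working(yf, eta, mu, family, theta)
        b_prev = beta.copy()
        b0_prev = b0
        b0 = _cd_sweeps(Xs, wp * w, z, beta, b0, lam, code, pen.a, pw,
                        CD_TOL, CD_MAX_SWEEPS)
        new_obj = _penalized_objective(yf, Xs, b0, beta, family, theta, spec_at, wp)
        # IRLS is not guaranteed monotone far from the optimum: halve the step
        # toward the previous iterate until the objective stops increasing
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 20:
            beta[:] = 0.5 * (beta + b_prev)
            b0 = 0.5 * (b0 + b0_prev)
            new_obj = _penalized_objective(yf, Xs, b0, beta, family, theta, spec_at, wp)
            halvings += 1
        if new_obj > obj + 1e-10:
            monotone = False
        param_change = max(np.max(np.abs(beta - b_prev)), abs(b0 - b0_prev))
        if (abs(new_obj - obj) <= OBJ_RTOL * (abs(obj) + 1.0)
                or param_change <= 1e-9):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    eta = np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    from .families import _weighted_loglik

    ll = _weighted_loglik(yf, mu, family, theta, wp)
    return b0, theta, ll, converged, monotone


# ---------------------------------------------------------------------------
# Lambda path
# ---------------------------------------------------------------------------


def make_lambda_path(
    data: CohortTable,
    spec: FamilySpec,
    pen: PenaltySpec,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> LambdaPath:
    """Log-spaced lambda grid from lambda_max down.

    lambda_max is the smallest lambda with an all-zero slope vector: the
    largest absolute working score over penalized coefficients at the null
    (intercept-only) model, weight-adjusted for the ALASSO.
    """
    if np.all(data.y == data.y[0]):
        raise ValueError("degenerate path: response is constant")
    Xs, _, _ = _standardize(data.X)
    y = data.y.astype(float)
    mu0 = np.full(data.n, max(y.mean(), 1e-8))
    base = spec.base_family
    theta = spec.theta
    if base == "negbin" and theta is None:
        theta = _profile_theta(y, mu0)
    s = _score_residual(y, mu0, base, theta)
    score = np.abs(Xs.T @ s) / data.n
    w = pen.weights if pen.weights is not None else np.ones(data.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(np.isinf(w), 0.0, score / np.maximum(w, 1e-300))
    lam_max = float(np.max(adj))
    if lam_max <= 0:
        lam_max = 1e-3
    lam_max *= 1.000001  # guard against ties at the boundary
    if n_lambda == 1:
        return LambdaPath(np.array([lam_max]))
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    return LambdaPath(grid)


# ---------------------------------------------------------------------------
# Path fitting
# ---------------------------------------------------------------------------


def fit_penalized(
    data: CohortTable,
    spec: FamilySpec,
    pen: PenaltySpec,
    path: Optional[LambdaPath] = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> PenalizedFit:
    """Solve the penalized likelihood over a lambda path with warm starts."""
    if pen.kind == "alasso" and pen.weights is None:
        pen = replace_weights_from_initial(data, spec, pen)
    if path is None:
        path = make_lambda_path(data, spec, pen, n_lambda, lambda_min_ratio)
    if spec.is_zero_inflated:
        return _fit_penalized_zi(data, spec, pen, path)

    Xs, center, scale = _standardize(data.X)
    y = data.y
    family = spec.family
    estimate_theta = family == "negbin" and spec.theta is None
    theta = spec.theta if spec.theta is not None else (1.0 if family == "negbin" else None)

    nl = path.n_lambda
    p = data.p
    intercepts = np.zeros(nl)
    slopes_std = np.zeros((nl, p))
    loglik = np.zeros(nl)
    thetas = np.zeros(nl) if family == "negbin" else None
    conv = np.zeros(nl, dtype=bool)

    beta = np.zeros(p)
    b0 = np.log(max(y.mean(), 1e-8))
    for i, lam in enumerate(path.grid):
        b0, theta, ll, ok, _ = _fit_one_lambda(
            y, Xs, family, pen, lam, b0, beta, theta, estimate_theta
        )
        if not ok:
            warnings.warn(f"penalized fit did not converge at lambda={lam:.4g}")
        intercepts[i] = b0
        slopes_std[i] = beta
        loglik[i] = ll
        conv[i] = ok
        if thetas is not None:
            thetas[i] = theta

    slopes = slopes_std / scale
    b0_orig = intercepts - slopes_std @ (center / scale)
    df = np.count_nonzero(slopes_std, axis=1)
    return PenalizedFit(
        lambdas=path.grid.copy(), intercepts=b0_orig, slopes=slopes,
        slopes_std=slopes_std, df=df, loglik=loglik, thetas=thetas,
        converged=conv, columns=list(data.columns), family=spec, penalty=pen,
        center=center, scale=scale,
    )


def replace_weights_from_initial(
    data: CohortTable, spec: FamilySpec, pen: PenaltySpec,
    initial: str = "mle", ridge: float = 1e-4,
) -> PenaltySpec:
    """Attach ALASSO weights from an initial consistent estimator.

    Default is the unpenalized family MLE on the standardized design
    (ridge-stabilized if singular); ``initial='ols'`` uses plain least
    squares of the raw counts instead.
    """
    Xs, _, _ = _standardize(data.X)
    y = data.y.astype(float)
    if initial == "ols":
        Xd = np.column_stack([np.ones(data.n), Xs])
        coefs, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        b = coefs[1:]
    else:
        std_tab = CohortTable(Xs, data.y, list(data.columns))
        try:
            fit = fit_mle(std_tab, spec if not spec.is_zero_inflated
                          else FamilySpec(spec.base_family, theta=spec.theta))
            b = fit.coefficients.slopes
        except (RankError, np.linalg.LinAlgError):
            b = _ridge_glm(std_tab, spec, ridge)
    w = adaptive_weights(b, pen.gamma)
    return PenaltySpec(pen.kind, pen.lam, pen.a, pen.gamma, w)


def _ridge_glm(data: CohortTable, spec: FamilySpec, alpha: float) -> np.ndarray:
    """L2-stabilized IRLS used when the MLE initial estimator is singular."""
    Xd = np.column_stack([np.ones(data.n), data.X])
    y = data.y.astype(float)
    beta = np.zeros(Xd.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    theta = spec.theta if spec.theta is not None else 1.0
    family = spec.base_family
    pen_mat = alpha * np.eye(Xd.shape[1])
    pen_mat[0, 0] = 0.0
    for _ in range(50):
        eta = np.clip(Xd @ beta, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        if family == "negbin" and spec.theta is None:
            theta = _profile_theta(y, mu)
        w, z = _working(y, eta, mu, family, theta)
        wX = Xd * w[:, None]
        new = np.linalg.solve(Xd.T @ wX + data.n * pen_mat, wX.T @ z)
        if np.max(np.abs(new - beta)) < 1e-9:
            beta = new
            break
        beta = new
    return beta[1:]


def _fit_penalized_zi(data: CohortTable, spec: FamilySpec, pen: PenaltySpec,
                      path: LambdaPath) -> PenalizedFit:
    """EM wrapper: penalized weighted count fit + penalized logistic zero fit."""
    Xs, center, scale = _standardize(data.X)
    y = data.y
    yf = y.astype(float)
    base = spec.base_family
    estimate_theta = base == "negbin" and spec.theta is None
    at_zero = y == 0
    p = data.p
    nl = path.n_lambda
    code = PENALTY_CODES[pen.kind]
    pw = np.asarray(pen.weights if pen.weights is not None else np.ones(p), float)

    from .families import _base_log_pmf, _weighted_loglik

    intercepts = np.zeros(nl)
    slopes_std = np.zeros((nl, p))
    zero_parts_std = np.zeros((nl, 1 + p))
    loglik = np.full(nl, -np.inf)
    thetas = np.zeros(nl) if base == "negbin" else None
    conv = np.zeros(nl, dtype=bool)

    beta = np.zeros(p)
    b0 = np.log(max(yf.mean(), 1e-8))
    gamma = np.zeros(1 + p)
    z0 = max(at_zero.mean() * 0.5, 1e-3)
    gamma[0] = np.log(z0 / (1 - z0))
    theta = spec.theta if spec.theta is not None else 1.0

    for i, lam in enumerate(path.grid):
        last_ll = -np.inf
        ok = False
        for _ in range(MAX_EM):
            mu = np.exp(np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP))
            phi = special.expit(np.clip(gamma[0] + Xs @ gamma[1:], -ETA_CLIP, ETA_CLIP))
            log_p0 = _base_log_pmf(np.zeros(data.n, dtype=np.int64), mu, base, theta)
            denom = phi + (1 - phi) * np.exp(log_p0)
            r = np.where(at_zero, phi / np.maximum(denom, 1e-300), 0.0)
            # M-step: count component with weights (1 - r)
            wc = np.maximum(1.0 - r, 1e-10)
            b0, theta, _, _, _ = _fit_one_lambda(
                y, Xs, base, pen, lam, b0, beta, theta, estimate_theta,
                prior_weights=wc, max_outer=5,
            )
            # M-step: penalized logistic fit of responsibilities
            for _ in range(3):
                etaz = np.clip(gamma[0] + Xs @ gamma[1:], -ETA_CLIP, ETA_CLIP)
                pz = special.expit(etaz)
                wz = np.maximum(pz * (1 - pz), 1e-8)
                zz = etaz + (r - pz) / wz
                g_slopes = gamma[1:].copy()
                gamma[0] = _cd_sweeps(Xs, wz, zz, g_slopes, gamma[0], lam, code,
                                      pen.a, pw, CD_TOL, CD_MAX_SWEEPS)
                gamma[1:] = g_slopes
            # observed-data log-likelihood
            phi = special.expit(np.clip(gamma[0] + Xs @ gamma[1:], -ETA_CLIP, ETA_CLIP))
            mu = np.exp(np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP))
            lp = _base_log_pmf(y, mu, base, theta)
            with np.errstate(divide="ignore"):
                ll_i = np.where(
                    at_zero,
                    np.logaddexp(np.log(np.maximum(phi, 1e-300)), np.log1p(-phi) + lp),
                    np.log1p(-phi) + lp,
                )
            ll = float(ll_i.sum())
            if not np.isfinite(ll):
                break
            if np.isfinite(last_ll) and abs(ll - last_ll) <= OBJ_RTOL * (abs(last_ll) + 1.0):
                ok = True
                break
            last_ll = ll
        if not ok:
            warnings.warn(f"zero-inflated EM did not converge at lambda={lam:.4g}")
        intercepts[i] = b0
        slopes_std[i] = beta
        zero_parts_std[i] = gamma
        loglik[i] = last_ll
        conv[i] = ok
        if thetas is not None:
            thetas[i] = theta

    slopes = slopes_std / scale
    b0_orig = intercepts - slopes_std @ (center / scale)
    zero_parts = zero_parts_std.copy()
    zero_parts[:, 1:] = zero_parts_std[:, 1:] / scale
    zero_parts[:, 0] = zero_parts_std[:, 0] - zero_parts_std[:, 1:] @ (center / scale)
    df = np.count_nonzero(slopes_std, axis=1)
    return PenalizedFit(
        lambdas=path.grid.copy(), intercepts=b0_orig, slopes=slopes,
        slopes_std=slopes_std, df=df, loglik=loglik, thetas=thetas,
        converged=conv, columns=list(data.columns), family=spec, penalty=pen,
        center=center, scale=scale, zero_parts=zero_parts,
    )


# ---------------------------------------------------------------------------
# Cross-validation and downstream
# ---------------------------------------------------------------------------


def _holdout_deviance(fit: PenalizedFit, test: CohortTable) -> np.ndarray:
    """-2 * held-out loglik per lambda, using training theta / zero part."""
    out = np.empty(fit.n_lambda)
    for i, lam in enumerate(fit.lambdas):
        coef = fit.coefficients(lam)
        fam = fit.family_at(lam)
        out[i] = -2.0 * float(np.sum(pointwise_log_likelihood(test, coef, fam)))
    return out


def cross_validate(
    data: CohortTable,
    spec: FamilySpec,
    pen: PenaltySpec,
    path: Optional[LambdaPath] = None,
    cv: Optional[CVSpec] = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    per_fold_weights: bool = True,
) -> CVResult:
    """Tune lambda by k-fold cross-validated predictive deviance.

    ALASSO weights are recomputed inside each training fold by default
    (``per_fold_weights=False`` reuses full-data weights).  The returned fit
    is the full-data path fit with ``selected_lambda`` set.
    """
    cv = cv or CVSpec()
    if pen.kind == "alasso" and pen.weights is None:
        pen_full = replace_weights_from_initial(data, spec, pen)
    else:
        pen_full = pen
    if path is None:
        path = make_lambda_path(data, spec, pen_full, n_lambda, lambda_min_ratio)

    labels = cv.assign(data.n)
    losses = np.full((cv.folds, path.n_lambda), np.nan)
    skipped = 0
    for k in range(cv.folds):
        train = data.subset(labels != k)
        test = data.subset(labels == k)
        if np.all(train.y == train.y[0]):
            warnings.warn(f"fold {k} skipped: degenerate training response")
            skipped += 1
            continue
        pen_k = pen_full
        if pen.kind == "alasso" and per_fold_weights:
            pen_k = replace_weights_from_initial(train, spec, pen)
        fit_k = fit_penalized(train, spec, pen_k, path)
        losses[k] = _holdout_deviance(fit_k, test)

    valid = ~np.isnan(losses).all(axis=1)
    mean_loss = np.nanmean(losses[valid], axis=0)
    se_loss = np.nanstd(losses[valid], axis=0, ddof=1) / np.sqrt(valid.sum())
    best = float(np.min(mean_loss))
    # ties resolve to the larger (sparser) lambda: first index at the minimum
    sel = int(np.argmax(mean_loss <= best + 1e-12))
    full_fit = fit_penalized(data, spec, pen_full, path)
    full_fit.selected_lambda = float(path.grid[sel])
    return CVResult(
        lambdas=path.grid.copy(), mean_loss=mean_loss, se_loss=se_loss,
        selected_lambda=float(path.grid[sel]), fit=full_fit,
        fold_losses=losses, skipped_folds=skipped,
    )


def select_support(fit: PenalizedFit, lam: Optional[float] = None) -> SelectionResult:
    """Names of covariates with nonzero slopes at the selected lambda."""
    i = fit.lambda_index(lam)
    nz = np.flatnonzero(fit.slopes_std[i] != 0.0)
    label = f"{fit.family.family}-{fit.penalty.kind}"
    scores = {fit.columns[j]: float(fit.slopes[i, j]) for j in nz}
    return SelectionResult([fit.columns[j] for j in nz], label, scores)


def refit_unpenalized(
    data: CohortTable,
    support: Sequence[str] | SelectionResult,
    forced_in: Sequence[str] = (),
    spec: Optional[FamilySpec] = None,
) -> FitResult:
    """Unpenalized refit on the selected support plus forced-in covariates."""
    if isinstance(support, SelectionResult):
        support = support.selected
    cols = list(dict.fromkeys(list(support) + list(forced_in)))
    if not cols:
        raise ValueError("support plus forced-in covariates is empty")
    spec = spec or FamilySpec("negbin")
    return fit_mle(data, spec, columns=cols)


def kkt_violations(fit: PenalizedFit, data: CohortTable,
                   lam: Optional[float] = None) -> tuple[float, float]:
    """Stationarity residuals at a path point (standardized scale).

    Returns ``(zero_violation, nonzero_violation)``: for zero coefficients
    the excess of |working score| over the penalty subgradient bound at 0+;
    for nonzero coefficients the absolute stationarity residual
    |score_j - P'(beta_j)|.
    """
    i = fit.lambda_index(lam)
    lam_val = float(fit.lambdas[i])
    Xs = (data.X - fit.center) / fit.scale
    beta = fit.slopes_std[i]
    b0 = float(fit.intercepts[i] + beta @ (fit.center / fit.scale))
    eta = np.clip(b0 + Xs @ beta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    theta = None if fit.thetas is None else float(fit.thetas[i])
    s = _score_residual(data.y.astype(float), mu, fit.family.base_family, theta)
    score = Xs.T @ s / data.n
    pen = fit.penalty.with_lambda(lam_val)
    from .penalties import _penalty_deriv_scalar

    code = PENALTY_CODES[pen.kind]
    w = pen.weights if pen.weights is not None else np.ones(data.p)
    zero_v = 0.0
    nonzero_v = 0.0
    for j in range(data.p):
        if np.isinf(w[j]):
            continue
        if beta[j] == 0.0:
            bound = lam_val * w[j] if code == 0 else lam_val * (w[j] if code == 0 else 1.0)
            zero_v = max(zero_v, abs(score[j]) - bound)
        else:
            d = _penalty_deriv_scalar(beta[j], code, lam_val, pen.a, w[j])
            nonzero_v = max(nonzero_v, abs(score[j] - d))
    return zero_v, nonzero_v
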