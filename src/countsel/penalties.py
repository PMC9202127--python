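"""Sparsity penalties for count regression: LASSO, adaptive LASSO, SCAD, MCP.

Each penalty P(beta) is an even, nondecreasing function of |beta| with
P(0) = 0:

* LASSO:   lambda * |b|
* ALASSO:  lambda * w_j * |b|, with weights w_j = 1 / |bhat_j|**gamma from an
  initial consistent estimator
* SCAD (a > 2):  lambda|b| on [0, lambda]; a quadratic blend on
  (lambda, a*lambda]; constant (a+1)*lambda**2/2 beyond
* MCP (a > 1):   lambda|b| - b**2/(2a) below a*lambda; constant
  a*lambda**2/2 beyond

The coordinate-descent solver repeatedly minimizes the univariate working
problem  0.5*v*(b - z/v)**2 + P(b);  ``threshold_update`` returns its exact
global minimizer by enumerating the stationary point of each branch (the
objective is piecewise quadratic) and breaking ties toward the sparser
(smaller |b|) solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .families import CoefficientVector

__all__ = [
    "PenaltySpec",
    "penalty_value",
    "penalty_derivative",
    "threshold_update",
    "adaptive_weights",
    "PENALTY_CODES",
]

DEFAULT_A = 3.7  # concavity parameter used for both SCAD and MCP
PENALTY_CODES = {"lasso": 0, "alasso": 0, "scad": 1, "mcp": 2}


@dataclass
class PenaltySpec:
    """A penalty family with its tuning parameters.

    ``lam`` is the overall strength; ``a`` the SCAD/MCP concavity
    (SCAD needs a > 2, MCP a > 1); ``gamma`` the ALASSO weight exponent;
    ``weights`` the per-coefficient ALASSO multipliers (1 otherwise, and an
    infinite weight permanently excludes a coefficient at any lam > 0).
    """

    kind: str = "mcp"
    lam: float = 0.0
    a: float = DEFAULT_A
    gamma: float = 1.0
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in PENALTY_CODES:
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.kind == "scad" and self.a <= 2:
            raise ValueError("SCAD requires a > 2")
        if self.kind == "mcp" and self.a <= 1:
            raise ValueError("MCP requires a > 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")

    def weight(self, j: Optional[int] = None) -> float:
        if self.weights is None or j is None:
            return 1.0
        return float(self.weights[j])

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.kind, lam, self.a, self.gamma, self.weights)


# ---------------------------------------------------------------------------
# Values and derivatives
# ---------------------------------------------------------------------------


@njit(cache=False)
def _penalty_value_scalar(b: float, code: int, lam: float, a: float, w: float) -> float:
    ab = abs(b)
    if code == 0:  # (a)lasso
        return lam * w * ab
    if code == 1:  # scad
        if ab <= lam:
            return lam * ab
        if ab <= a * lam:
            return -(ab * ab - 2.0 * a * lam * ab + lam * lam) / (2.0 * (a - 1.0))
        return (a + 1.0) * lam * lam / 2.0
    # mcp
    if ab < a * lam:
        return lam * ab - b * b / (2.0 * a)
    return a * lam * lam / 2.0


@njit(cache=False)
def _penalty_deriv_scalar(b: float, code: int, lam: float, a: float, w: float) -> float:
    """d/d|b| of the penalty, times sign(b); undefined at 0 (caller handles)."""
    s = 1.0 if b > 0 else -1.0
    ab = abs(b)
    if code == 0:
        return s * lam * w
    if code == 1:
        if ab <= lam:
            return s * lam
        if ab <= a * lam:
            return s * (a * lam - ab) / (a - 1.0)
        return 0.0
    if ab < a * lam:
        return s * (lam - ab / a)
    return 0.0


def penalty_value(beta, spec: PenaltySpec, j: Optional[int] = None):
    """Penalty value at ``beta`` (vectorized; ALASSO uses weight ``j``)."""
    w = spec.weight(j)
    code = PENALTY_CODES[spec.kind]
    f = np.vectorize(lambda b: _penalty_value_scalar(float(b), code, spec.lam, spec.a, w))
    out = f(beta)
    return float(out) if np.isscalar(beta) else out


def penalty_derivative(beta, spec: PenaltySpec, j: Optional[int] = None):
    """Penalty derivative at nonzero ``beta`` (sign rule included)."""
    if np.any(np.asarray(beta) == 0):
        raise ValueError("penalty derivative undefined at 0; use subgradient logic")
    w = spec.weight(j)
    code = PENALTY_CODES[spec.kind]
    f = np.vectorize(lambda b: _penalty_deriv_scalar(float(b), code, spec.lam, spec.a, w))
    out = f(beta)
    return float(out) if np.isscalar(beta) else out


def penalty_total(slopes: np.ndarray, spec: PenaltySpec) -> float:
    """Sum of per-coefficient penalties (ALASSO weights applied positionally)."""
    code = PENALTY_CODES[spec.kind]
    total = 0.0
    for j, b in enumerate(np.asarray(slopes, dtype=float)):
        w = spec.weight(j if spec.weights is not None else None)
        if np.isinf(w):
            if b != 0.0:
                return np.inf
            continue
        total += _penalty_value_scalar(b, code, spec.lam, spec.a, w)
    return total


# ---------------------------------------------------------------------------
# Exact univariate thresholding
# ---------------------------------------------------------------------------


@njit(cache=False)
def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def _uni_objective(b: float, z: float, v: float, code: int, lam: float, a: float, w: float) -> float:
    return 0.5 * v * b * b - z * b + _penalty_value_scalar(b, code, lam, a, w)


@njit(cache=False)
def _threshold_scalar(z: float, v: float, code: int, lam: float, a: float, w: float) -> float:
    """Exact global minimizer of 0.5*v*b^2 - z*b + P(b).

    Enumerates the stationary point of every quadratic branch (kept only if
    it lies inside its branch), plus b = 0, and picks the candidate with the
    lowest objective; ties go to the smaller |b|.
    """
    lw = lam * w
    if code == 0:
        return _soft(z, lw) / v
    s = 1.0 if z >= 0 else -1.0
    az = abs(z)
    # candidates: 0, branch-wise stationary points
    cand = np.empty(4)
    ncand = 0
    cand[ncand] = 0.0
    ncand += 1
    if code == 1:  # scad: branches [0,lam], (lam,a*lam], beyond
        b1 = _soft(z, lam) / v
        if abs(b1) <= lam:
            cand[ncand] = b1; ncand += 1
        denom = v - 1.0 / (a - 1.0)
        if denom > 0.0:
            b2 = s * (az - a * lam / (a - 1.0)) / denom
            if s * b2 > lam and s * b2 <= a * lam:
                cand[ncand] = b2; ncand += 1
        b3 = z / v
        if abs(b3) > a * lam:
            cand[ncand] = b3; ncand += 1
        # boundary of the flat branch can be the minimizer when denom <= 0
        cand_extra = s * a * lam
        best = cand[0]
        fbest = _uni_objective(best, z, v, code, lam, a, w)
        for i in range(1, ncand):
            fi = _uni_objective(cand[i], z, v, code, lam, a, w)
            if fi < fbest - 1e-15 or (abs(fi - fbest) <= 1e-15 and abs(cand[i]) < abs(best)):
                best = cand[i]; fbest = fi
        fe = _uni_objective(cand_extra, z, v, code, lam, a, w)
        if fe < fbest - 1e-15:
            best = cand_extra
        return best
    # mcp: branches [0, a*lam), beyond
    b1 = 0.0
    denom = v - 1.0 / a
    have_b1 = False
    if denom > 0.0:
        b1 = s * _soft(az, lam) / denom
        if abs(b1) < a * lam:
            cand[ncand] = b1; ncand += 1
    b2 = z / v
    if abs(b2) >= a * lam:
        cand[ncand] = b2; ncand += 1
    cand_extra = s * a * lam
    best = cand[0]
    fbest = _uni_objective(best, z, v, code, lam, a, w)
    for i in range(1, ncand):
        fi = _uni_objective(cand[i], z, v, code, lam, a, w)
        if fi < fbest - 1e-15 or (abs(fi - fbest) <= 1e-15 and abs(cand[i]) < abs(best)):
            best = cand[i]; fbest = fi
    fe = _uni_objective(cand_extra, z, v, code, lam, a, w)
    if fe < fbest - 1e-15:
        best = cand_extra
    return best


def threshold_update(z: float, v: float, spec: PenaltySpec, j: Optional[int] = None) -> float:
    """Exact minimizer of the univariate penalized working problem.

    Solves ``argmin_b 0.5*v*(b - z/v)**2 + P(b)`` for working curvature
    ``v > 0``.  For the LASSO this is the soft threshold S(z, lam*w)/v; MCP
    and SCAD additionally have a linearly rescaled middle region and an
    unbiased region where the update equals z/v.  Region-boundary ties
    resolve to the sparser solution.
    """
    if v <= 0:
        raise ValueError("working curvature v must be positive")
    w = spec.weight(j)
    if np.isinf(w):
        return 0.0
    return float(_threshold_scalar(float(z), float(v), PENALTY_CODES[spec.kind],
                                   spec.lam, spec.a, w))


def adaptive_weights(initial: CoefficientVector | np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """ALASSO weights w_j = 1/|bhat_j|**gamma from an initial estimator.

    A zero initial coefficient maps to an infinite weight, permanently
    excluding that coefficient at any lam > 0.  gamma = 0 degenerates to the
    plain LASSO (all weights 1).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    slopes = initial.slopes if isinstance(initial, CoefficientVector) else np.asarray(initial, float)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(slopes) ** gamma
    return w
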