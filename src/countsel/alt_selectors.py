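"""Competitor variable selectors: backward stepwise elimination and
random-forest minimal depth.

Backward stepwise starts from the full count-regression model and
iteratively drops the worst term (largest Wald p-value, or the removal that
most improves AIC) until every remaining term passes the criterion.
Multi-column groups (dummy blocks of one factor) are dropped together via a
likelihood-ratio test.

The forest selector grows a regression forest on the raw counts.  The
minimal depth of a variable in a tree is the depth of the first node that
splits on it (root = 0); variables never split in a tree score the tree
depth + 1.  Variables whose average minimal depth falls below a threshold —
by default the forest-wide mean over all variables — are selected
(Ishwaran's minimal-depth idea with a mean-threshold simplification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .families import CohortTable, FamilySpec, fit_mle
from .penalized_fit import SelectionResult

__all__ = [
    "ForestParams",
    "ForestFit",
    "backward_stepwise",
    "fit_forest",
    "minimal_depth_select",
]


@dataclass
class ForestParams:
    """Regression-forest settings for minimal-depth selection."""

    n_trees: int = 1000
    mtry: Optional[int] = None  # default ceil(p/3), the regression convention
    min_node_size: int = 5
    seed: int = 0
    threshold: Optional[float] = None  # None -> forest-wide mean minimal depth

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.ceil(p / 3))
        if not 1 <= m <= p:
            raise ValueError("mtry must lie in [1, p]")
        return m


@dataclass
class ForestFit:
    """A fitted forest plus its out-of-bag error."""

    model: RandomForestRegressor
    oob_mse: float
    columns: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Backward stepwise
# ---------------------------------------------------------------------------


def backward_stepwise(
    data: CohortTable,
    spec: FamilySpec,
    alpha: float = 0.05,
    criterion: str = "wald",
    groups: Optional[dict[str, str]] = None,
) -> SelectionResult:
    """Backward elimination on the full count-regression model.

    ``criterion='wald'`` removes the largest-p term while any p exceeds
    ``alpha``; ``criterion='aic'`` removes the term whose deletion lowers AIC
    most, while any deletion lowers it.  ``groups`` maps column names to
    group labels; a multi-column group is tested by a likelihood-ratio test
    and removed as a block.  Ties resolve to the lowest column index.
    """
    if criterion not in ("wald", "aic"):
        raise ValueError("criterion must be 'wald' or 'aic'")
    cols = list(data.columns)
    groups = groups or {}
    current = list(cols)
    fit = fit_mle(data, spec, columns=current)
    if not fit.converged:
        raise RuntimeError(
            f"full model did not converge (loglik={fit.loglik:.3f}); "
            "backward stepwise needs an estimable full model"
        )
    pvalues: dict[str, float] = {}
    while current:
        # group the current columns
        blocks: dict[str, list[str]] = {}
        for c in current:
            blocks.setdefault(groups.get(c, c), []).append(c)
        if criterion == "wald":
            scores: list[tuple[float, int, str]] = []
            for label, block in blocks.items():
                if len(block) == 1 and label == block[0]:
                    j = fit.names.index(block[0])
                    pv = float(fit.p_value[j])
                else:
                    reduced_cols = [c for c in current if c not in block]
                    pv = _lrt_pvalue(data, spec, fit, reduced_cols, len(block))
                scores.append((pv, min(cols.index(c) for c in block), label))
            scores.sort(key=lambda t: (-t[0], t[1]))
            worst_p, _, worst = scores[0]
            for pv, _, label in scores:
                pvalues[label] = pv
            if worst_p <= alpha:
                break
            current = [c for c in current if c not in blocks[worst]]
        else:  # aic
            best_drop = None
            best_aic = fit.aic
            for label, block in sorted(
                blocks.items(), key=lambda kv: min(cols.index(c) for c in kv[1])
            ):
                reduced_cols = [c for c in current if c not in block]
                if reduced_cols:
                    f2 = fit_mle(data, spec, columns=reduced_cols)
                    cand_aic = f2.aic
                else:
                    cand_aic = _null_aic(data, spec)
                if cand_aic < best_aic - 1e-9:
                    best_aic = cand_aic
                    best_drop = label
            if best_drop is None:
                break
            current = [c for c in current if c not in blocks[best_drop]]
        if not current:
            break
        fit = fit_mle(data, spec, columns=current)
    return SelectionResult(
        current, f"{spec.family}-stepwise",
        scores={k: v for k, v in pvalues.items() if k in
                {groups.get(c, c) for c in current} | set(current)} or None,
    )


def _lrt_pvalue(data, spec, full_fit, reduced_cols, df):
    if reduced_cols:
        reduced = fit_mle(data, spec, columns=reduced_cols)
        ll0 = reduced.loglik
    else:
        ll0 = _null_loglik(data, spec)
    stat = max(2.0 * (full_fit.loglik - ll0), 0.0)
    return float(stats.chi2.sf(stat, df))


def _null_fit(data: CohortTable, spec: FamilySpec):
    null_tab = CohortTable(np.zeros((data.n, 0)), data.y, [])
    return fit_mle(null_tab, spec)


def _null_loglik(data, spec):
    return _null_fit(data, spec).loglik


def _null_aic(data, spec):
    return _null_fit(data, spec).aic


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


def fit_forest(data: CohortTable, params: Optional[ForestParams] = None) -> ForestFit:
    """Regression forest on the raw counts, with out-of-bag MSE."""
    params = params or ForestParams()
    mtry = params.resolved_mtry(data.p)
    model = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=mtry,
        min_samples_leaf=params.min_node_size,
        oob_score=params.n_trees > 1,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse OOB coverage at tiny n_trees
        model.fit(data.X, data.y.astype(float))
    if params.n_trees > 1 and hasattr(model, "oob_prediction_"):
        oob = model.oob_prediction_
        covered = ~np.isnan(oob)
        oob_mse = float(np.mean((data.y[covered] - oob[covered]) ** 2))
    else:
        oob_mse = float("nan")
    return ForestFit(model, oob_mse, list(data.columns))


def _tree_minimal_depths(tree, p: int) -> np.ndarray:
    """Per-variable minimal depth in one tree; unsplit -> tree depth + 1."""
    t = tree.tree_
    depth = np.zeros(t.node_count, dtype=np.int64)
    stack = [(0, 0)]
    max_depth = 0
    first = np.full(p, np.inf)
    while stack:
        node, d = stack.pop()
        depth[node] = d
        max_depth = max(max_depth, d)
        if t.children_left[node] != -1:
            v = t.feature[node]
            if d < first[v]:
                first[v] = d
            stack.append((t.children_left[node], d + 1))
            stack.append((t.children_right[node], d + 1))
    return np.where(np.isinf(first), max_depth + 1, first)


def minimal_depth_select(
    forest: ForestFit, params: Optional[ForestParams] = None
) -> SelectionResult:
    """Select variables whose mean minimal depth is below the threshold.

    The default threshold is the forest-wide mean of the per-variable
    scores; a constant (never-split) covariate always scores tree depth + 1
    and is never selected.
    """
    params = params or ForestParams()
    p = len(forest.columns)
    depths = np.vstack([
        _tree_minimal_depths(est, p) for est in forest.model.estimators_
    ])
    scores = depths.mean(axis=0)
    threshold = params.threshold if params.threshold is not None else float(scores.mean())
    selected = [forest.columns[j] for j in range(p) if scores[j] < threshold]
    return SelectionResult(
        selected, "rf-minimal-depth",
        scores={forest.columns[j]: float(scores[j]) for j in range(p)},
    )
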