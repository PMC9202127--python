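# Methods

## Problem setting

`countsel` models a nonnegative integer outcome — the motivating example is
the number of psychiatric rehospitalizations of patients with schizophrenia
— as a function of demographic and clinical covariates, and asks which
covariates matter. Count outcomes of this kind are strongly right-skewed,
over-dispersed (variance well above the mean) and zero-heavy, so the package
carries four likelihood families and four sparsity penalties, plus two
non-penalized competitor selectors, and the machinery to compare all of them.

## Count families

* **Poisson**: `E[Y] = Var[Y] = mu`, log link `log mu = b0 + x'b`.
* **Negative binomial (NB)**: mean `mu`, shape `theta` (`k` in the classical
  NB2 form), `Var = mu + mu^2/theta`. `theta -> inf` recovers the Poisson.
  Note the parameterization: some software reports `alpha = 1/theta`.
* **Zero-inflated ZIP/ZINB**: a two-component mixture with structural-zero
  probability `phi`, so `P(0) = phi + (1-phi) P_base(0)` and
  `P(y) = (1-phi) P_base(y)` for `y >= 1`. The zero component is a logistic
  model, by default on the same covariates as the count part
  (`phi_model="covariates"`), with an intercept-only option; the choice of
  zero-part design is a genuine modeling decision for which no single
  convention exists.

Unpenalized maximum likelihood uses IRLS with a log link. For the NB,
`theta` is profiled by alternating a bounded scalar maximization (log-scale,
`theta` in `[1e-3, 1e6]`) with the beta step. Standard errors for the count
coefficients come from the Fisher information at the optimum with `theta`
held fixed — the usual NB-GLM convention; `theta`'s own SE comes from the
curvature of its profile log-likelihood. Zero-inflated families are fit by
EM (E-step: structural-zero responsibilities; M-step: weighted count GLM
with fractional weights plus weighted-logistic zero fit), with standard
errors from a central-finite-difference observed information of the full
mixture log-likelihood. Convergence is declared at a relative log-likelihood
change below `1e-8`, capped at 100 outer (200 EM) iterations;
non-convergence sets a flag on the result instead of raising.

## Penalties and the thresholding operator

Four penalties on the slope vector (intercepts, `theta`, and zero-part
intercepts are never penalized):

| penalty | form | tuning |
|---|---|---|
| LASSO | `lam * \|b\|` | `lam` |
| ALASSO | `lam * w_j * \|b\|`, `w_j = 1/\|bhat_j\|^gamma` | `lam`, `gamma` (default 1) |
| SCAD | 3-branch folded concave | `lam`, `a > 2` (default 3.7) |
| MCP | `lam\|b\| - b^2/(2a)` below `a*lam`, constant `a lam^2/2` beyond | `lam`, `a > 1` (default 3.7) |

`a = 3.7` is used for both SCAD and MCP (MCP literature often prefers 3;
both are configurable). The ALASSO initial estimator is the unpenalized
family MLE on the standardized design (ridge-stabilized when singular);
"plain least squares on the raw counts" is available as a documented option
but is a poor initializer for a log-link model. Weights are recomputed
inside each CV training fold by default (`per_fold_weights=False` reuses
full-data weights) — the choice matters when folds are small, and the
per-fold variant is the one that keeps the held-out fold untouched.

The coordinate-descent updates are the *exact* minimizers of the univariate
working problem `0.5 v (b - z/v)^2 + P(b)`. Because the objective is
piecewise quadratic, the minimizer is found by enumerating each branch's
stationary point (kept only when it lands inside its branch), the origin,
and the branch boundary, and picking the lowest objective; boundary ties
resolve to the smaller-`|b|` (sparser) solution. This enumeration is exact
even in the awkward regime `v < 1/a` where the MCP/SCAD branch curvature
turns negative and the usual closed-form updates are invalid.

Inside the path solver that regime is additionally *damped*: when the GLM
working curvature of a coordinate falls below `1/a` (MCP) or `1/(a-1)`
(SCAD) — which happens under strong overdispersion, where NB working
weights are small — the univariate subproblem is non-convex and its exact
minimizer can jump arbitrarily far, destabilizing the outer loop. The
solver therefore floors the proximal curvature at `1.05/a`
(resp. `1.05/(a-1)`). This is a majorize-minimize step: it shrinks the step
size but leaves the fixed points — and hence the KKT conditions every
returned solution is tested against — unchanged.

## Penalized solver

The objective is `-(1/n) loglik + sum_j P_lam(b_j)`, minimized over a
log-spaced 100-point lambda grid from `lambda_max` (the largest absolute
null-model working score over penalized coordinates, weight-adjusted for
ALASSO, at which the solution is exactly all-zero) down to
`0.01 * lambda_max`, with warm starts. Covariates are standardized to zero
mean and unit variance internally — the penalties are scale-sensitive and
dummy columns are treated like continuous ones — and coefficients are
returned on the original scale.

Each lambda is solved by outer IRLS (working weights/response from the
current means; NB `theta` re-profiled every outer cycle) around an inner
cyclic coordinate descent (numba-compiled; residual updates keep each
coordinate step `O(n)`). IRLS is not guaranteed monotone far from the
optimum, so a step-halving fallback toward the previous iterate is applied
whenever the penalized objective would rise; fits that still fail to settle
are flagged, never silently accepted. KKT stationarity of every returned
solution is checkable via `kkt_violations` (used throughout the tests at a
`1e-4` tolerance). No global-optimality claim is made for the non-convex
SCAD/MCP objectives; warm starts along the path are the only continuation
strategy, as is standard practice.

Zero-inflated penalized fits wrap the same machinery in EM; both slope sets
share one lambda. These fits are the most fragile — with near-boundary
mixing proportions the observed-data likelihood can plateau — and EM
non-convergence at a path point is recorded on the result and propagated as
"not converged" in downstream comparison tables rather than raised.

Lambda is tuned by tenfold cross-validation on held-out predictive deviance
(`-2 *` held-out log-likelihood, using the training fold's `theta`), rule:
minimum mean loss, ties to the larger (sparser) lambda. No one-standard-
error rule is applied. Folds with a degenerate (constant) training response
are skipped with a warning.

## Competitor selectors

**Backward stepwise** starts from the full model and removes the worst term
(largest Wald p at `alpha = 0.05` by default; an AIC criterion is a flag)
one at a time, refitting after each removal; multi-column dummy blocks are
removed whole via a likelihood-ratio test. Ties resolve to the lowest
column index, making the procedure invariant to covariate order.

**Random-forest minimal depth** grows a regression forest on the raw counts
(defaults: 1000 trees, `mtry = ceil(p/3)`, minimum node size 5; the
benchmark uses 500 trees). A variable's minimal depth in a tree is the
depth of the first node splitting on it (root = 0; never split maps to
tree depth + 1); its score is the average over trees, and variables scoring
below the forest-wide mean score are selected. The mean-score threshold is
a deliberate simplification of the maximal-subtree null-distribution rule;
the threshold is exposed as configuration because reasonable rules differ
visibly in how aggressively they select.

## Simulation benchmark

Six scenarios: `p in {20, 50}` x `rho in {0.2, 0.5, 0.7}` (exchangeable
correlation by default, AR(1) by flag), `n = 500` training subjects per
replicate with a paired `n = 1000` evaluation set (selection accuracy needs
no held-out data; the evaluation tables serve predictive reporting), NB
response with `theta = 1`, intercept 0.5, and true slopes
`(0.8, -0.8, 0.6, -0.6, 0.5)` on the first five covariates — magnitudes
chosen so that every selector attains sensitivity 1.00 at `n = 500` while
specificity separates the methods. Per-replicate seeds derive from
`default_rng([seed, rep, stream])`, so the whole benchmark is reproducible
bit-for-bit from one master seed. Scoring per replicate: FN/TP/FP/TN
counts against the truth, total accuracy `(TP+TN)/p`, sensitivity `TP/5`,
specificity `TN/(p-5)`; failed replicates are excluded from means and
counted. The default test-suite and acceptance runs use 20 replicates per
scenario — the package's chosen problem size for routine verification —
while the full 100-replicate grid is available through
`run_benchmark`/the `benchmark` CLI.

## Model comparison

The Vuong statistic compares two fitted models on the same subjects via
the pointwise log-likelihood differences `m_i`:
`z = sqrt(n) * (mean(m) - c) / sd(m)`, with `c = (k1-k2) log(n) / (2n)` for
the BIC correction (`(k1-k2)/n` for AIC, 0 for none), one-sided
`p = 1 - Phi(z)`. For penalized models `k` counts nonzero coefficients plus
intercept plus `theta` (plus the zero part where present) — a convention
that must be fixed somewhere since penalized and full models are compared
on complexity. Identical pointwise likelihoods raise a degenerate-test
error rather than returning 0/0.

`nested_cv_rmse` compares NB-MCP and the forest predictively: 5 outer
folds, all tuning (lambda by 10-fold inner CV, forest `mtry` by OOB error
over a small grid) confined to the outer-training rows, RMSE on the outer
test rows, paired two-sided t-test across folds.

## Synthetic cohort

The real cohort is not publicly deposited, so `cohort_synth` generates a
synthetic stand-in from its published summary structure: `n = 413`;
covariates sampled independently with the published marginal frequencies
(age and age-at-onset jointly with correlation 0.7, to exercise the
exclusion rule; durations truncated below at their published minima); an NB
response with `theta = 0.99` and the published multivariate coefficients as
the generative law; missing cells injected completely at random at
per-column rates inside the published 0.72%–6.77% range, with the extremes
placed on medical-disease history (lowest) and family psychiatric history
(highest) as published, and intermediate rates (1.2%–3%) assigned once to a
plausible subset of the remaining columns. At large `n` the synthetic
response reproduces the published ballpark (mean ≈ 1.2, ≈ 52% zeros).

What the generator does **not** emulate: real covariate dependence (other
than the age pair), any misreporting or censoring of the response, and the
exact joint distribution that produced the published estimates. Passing
tests therefore demonstrate correctness of the machinery and recoverability
of the generative law — not claims about the real cohort; the published
final-model table (its exact estimates, AIC/BIC) is *not* a reproduction
target.

Workflow conventions:

* **Imputation** is the simple method: column mean for quantitative
  variables, level-median for qualitative ones on the declared level order
  (an even-count tie takes the lower level — a documented convention, since
  a median of an unordered nominal variable is only defined relative to
  some ordering).
* **Design construction** dummy-codes against declared reference levels,
  adds the three gender interactions (education, suicide history,
  antipsychotic-drug non-adherence), drops `age` when its correlation with
  age-at-onset exceeds 0.7, and tags the three forced-in clinical
  covariates (non-adherence, substance use, smoking) that enter the final
  refit regardless of selection.
* **Descriptives** use the adjusted Fisher–Pearson skewness
  `G1 = g1 sqrt(n(n-1))/(n-2)` (the SPSS-style convention that matches the
  published 4.49); unadjusted `g1` by flag. The published table truncates
  rather than rounds at two decimals (SD 2.1874 is printed "2.18"), so
  numeric checks compare at within-0.01 precision.
* **Pipeline** = impute → design → NB-MCP tenfold-CV selection →
  unpenalized NB refit (+forced-in) → Vuong comparisons vs P-MCP, ZIP-MCP
  and the full NB/Poisson models → descriptive and rate-ratio tables, with
  a manifest of every seed. Reruns with the same configuration are
  byte-identical.

## Numerical choices at a glance

| quantity | value | where |
|---|---|---|
| linear-predictor clip | ±30 | all exp() calls |
| outer IRLS tolerance | rel. loglik/objective 1e-8 | MLE and penalized |
| coordinate-descent tolerance | max coefficient change 1e-7 | inner loop |
| lambda grid | 100 points, `lambda_min_ratio` 0.01 | path solver |
| CV | 10 folds, min mean deviance, ties → sparser | tuning |
| `a` | 3.7 (SCAD and MCP) | penalties |
| theta search range | [1e-3, 1e6], log scale | profiling |
| EM cap | 200 iterations | zero-inflated fits |

## Known limitations

* SCAD/MCP solutions are local optima of a non-convex objective; different
  warm-start paths can select slightly different supports near ties.
* Refit p-values after selection are the naive two-stage values, with no
  post-selection correction — deliberately matching common applied
  practice for this workflow.
* The zero-inflated penalized EM can fail to converge on cohorts with weak
  zero-inflation; this surfaces as a flagged, excluded comparison.
* Categorical selection is per-dummy, not per-factor, in the penalized
  methods (individual levels can enter alone); stepwise optionally groups
  dummies.
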