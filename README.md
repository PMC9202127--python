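# countsel

Variable selection for count regression: penalized Poisson, negative
binomial (NB) and zero-inflated models with LASSO, adaptive LASSO, SCAD and
MCP penalties, benchmarked against backward stepwise elimination and
random-forest minimal-depth selection.

## The problem

Hospital-readmission counts — the motivating application is the number of
psychiatric rehospitalizations of patients with schizophrenia — are
over-dispersed, zero-heavy and right-skewed, and come with dozens of
candidate demographic and clinical covariates. Choosing which covariates
matter via classical stepwise search is unstable; penalized likelihood does
selection and estimation in one step by solving

    min_b  -(1/n) * l(b)  +  sum_j P_lam(b_j)

where `l` is the Poisson / NB / zero-inflated log-likelihood with log link
`log mu_i = b0 + x_i'b`, and `P_lam` is one of

* LASSO `lam|b|`,
* adaptive LASSO `lam w_j |b|` with `w_j = 1/|bhat_j|^gamma`,
* SCAD (folded concave, `a = 3.7`),
* MCP `lam|b| - b^2/(2a)` for `|b| < a*lam`, constant beyond (`a = 3.7`).

The solver is outer IRLS (with the NB shape `theta` profiled each cycle)
around a numba-compiled cyclic coordinate descent whose univariate updates
are exact thresholding operators; `lam` is tuned by tenfold
cross-validation on held-out deviance. A simulation benchmark scores every
selector by FN/TP/FP/TN, total accuracy, sensitivity and specificity
against a known truth, and fitted models are compared by the BIC-corrected
Vuong test and nested-CV RMSE. Because the motivating cohort is not
publicly deposited, a synthetic-cohort module emulates its published
summary structure (marginals, NB generative law with `theta = 0.99`,
missingness) and drives the full study pipeline end to end.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
import numpy as np
from countsel import (FamilySpec, PenaltySpec, CVSpec, cross_validate,
                      select_support, refit_unpenalized, rate_ratios)
from countsel.sim_benchmark import ScenarioSpec, generate_scenario_data

# NB data: 500 subjects, 20 covariates, true slopes (0.8,-0.8,0.6,-0.6,0.5)
train, _ = generate_scenario_data(ScenarioSpec(p=20, rho=0.2, seed=1), rep=0)

res = cross_validate(train, FamilySpec("negbin"), PenaltySpec(kind="mcp"),
                     cv=CVSpec(folds=10, seed=1))
support = select_support(res.fit)
print(support.selected)          # -> ['x1', 'x2', 'x3', 'x4', 'x5']

refit = refit_unpenalized(train, support, spec=FamilySpec("negbin"))
print(refit.to_table().round(3).to_string(index=False))
```

which prints (the five informative covariates, and nothing else, survive
cross-validated NB-MCP selection; the refit recovers the generative slopes
within sampling error):

```
       term  estimate    se       z  p_value
(Intercept)     0.532 0.062   8.538      0.0
         x1     0.899 0.063  14.323      0.0
         x2    -0.751 0.064 -11.649      0.0
         x3     0.542 0.062   8.808      0.0
         x4    -0.596 0.057 -10.381      0.0
         x5     0.482 0.060   7.994      0.0
```

`rate_ratios(refit)` exponentiates the estimates into multiplicative
effects on the expected count with Wald 95% intervals — e.g. a coefficient
of 0.08 is a rate ratio of 1.08 per unit increase.

The same workflow is available from the shell:

```sh
countsel synth --n 413 --seed 1 --out-csv cohort.csv
countsel fit cohort.csv --family negbin --penalty mcp --folds 10
countsel benchmark --p 20 --rho 0.2 --reps 20 --methods mcp,stepwise,rf
countsel pipeline --seed 1 --out-dir results/study
```

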