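# riaftbart

Bayesian causal survival analysis for **multiple treatments** on **clustered,
right-censored** outcomes.

Comparative-effectiveness questions in registry and multi-site data combine
four difficulties at once: more than two active treatments, survival outcomes
with heavy right-censoring, strong institution-level variation, and the
ever-present threat of unmeasured confounding.  `riaftbart` addresses all
four with a random-intercept accelerated failure time (AFT) model whose
regression function is a sum of regularized trees (BART):

```
log T_ik = f(A_ik, X_ik) + b_k + eps_ik,
b_k ~ N(0, alpha * tau^2),   eps_ik ~ N(0, sigma^2)
```

for subject *i* in cluster *k* with treatment `A`, covariates `X`, failure
time `T` in months.  `f` is a sum of H shallow trees with regularizing
priors, so nonlinearities and treatment-covariate interactions are learned
from the data; `b_k` captures cluster-specific main effects; `alpha` is a
parameter-expansion scalar that speeds MCMC mixing of the intercept variance
`tau^2`.  Right-censored subjects are handled inside the sampler by
truncated-normal data augmentation.  From the posterior the package reports
pairwise conditional average treatment effects (CATE, and CATT for the
treated) on three scales — difference in expected log survival time,
difference in survival probability at a horizon t\*, and difference in
restricted mean survival time (RMST, area under the survival curve up to
t\*) — plus counterfactual survival curves, cluster-effect summaries, and
convergence diagnostics.

Because "no unmeasured confounding" is untestable, the package includes a
confounding-function sensitivity analysis: you posit signs and bounds
(in units of the residual SD) for

```
c(a_j, a_m, x, v) = E[log T(a_j) | A=a_j, x, v] - E[log T(a_j) | A=a_m, x, v],
```

and a nested multiple-imputation loop (Q1 generalized-propensity-score draws
x Q2 confounding-function draws) corrects the outcomes, refits, and pools the
posteriors — showing how your causal conclusions move as the posited
confounding grows.

A full simulation engine ships with the package: clustered Weibull outcomes
under proportional or non-proportional hazards, a random-intercept
multinomial treatment model calibrated to a 6:3:1 allocation, censoring
calibrated to 10%/40%, closed-form ground-truth effects, and a
relative-bias/coverage study harness.

## Worked example

Simulate one replicate of the clustered Weibull design (8 clusters of 150,
10% censoring), fit the model, and estimate the three pairwise 5-year RMST
effects:

```python
import numpy as np
from dataclasses import replace
import riaftbart as rb

cfg = replace(rb.DGPConfig(K=8, n_k=150), censoring_target=0.10)
sim = rb.simulate_dataset(cfg, np.random.default_rng(42))

model = rb.RiAFTBART(sim.data, n_trees=50)     # or RiAFTBART.from_dataframe(df, ...)
res = model.fit(draws=500, burn=300, seed=7)
print(res.summary().head(4).to_string(index=False))
for pair in [(1, 2), (1, 3), (2, 3)]:
    r = res.cate(*pair, scale="rmst", t_star=60.0)
    print("CATE%s 5-yr RMST: %.2f months (95%% CI %.2f, %.2f)"
          % (pair, r.estimate, r.ci[0], r.ci[1]))
```

prints

```
parameter     mean       sd  ci_2.5%  ci_97.5%      units
    sigma 0.693470 0.015994 0.662282  0.724185 log-months
      tau 1.326533 0.577440 0.586452  2.744175 log-months
    alpha 2.010475 1.773062 0.352719  6.410453          -
     b[1] 2.231044 0.162461 1.924404  2.519176 log-months
CATE(1, 2) 5-yr RMST: 4.85 months (95% CI 3.57, 6.24)
CATE(1, 3) 5-yr RMST: 2.41 months (95% CI 0.35, 4.24)
CATE(2, 3) 5-yr RMST: -2.45 months (95% CI -4.53, -0.47)
```

`sigma` is the residual SD of log survival time, `tau` the cluster-intercept
SD (both log-months), and `b[1]` the first cluster's shift in expected log
survival.  The RMST contrasts say arm 1 buys about 4.9 more months of
expected survival within 5 years than arm 2; all three intervals here
exclude zero and bracket this replicate's generating truths (4.0, 2.5, -1.5
months).  `res.catt(...)`, `res.survival_curve(...)` and
`res.diagnostics()` give effects on the treated, counterfactual survival
curves, and split-chain R-hat/ESS.

Sensitivity analysis with a YAML spec (`c_1_2: {sign: "+", omega: 0.75}`
bounds c(1,2) in (0, 0.75 sigma-hat)):

```python
spec = rb.ConfoundingFunctionSpec.from_yaml("spec.yaml")
out = rb.run_sensitivity(sim.data, spec, Q1=30, Q2=30, seed=1)
```

Everything is also scriptable from the shell: `riaftbart fit`, `cate`,
`sensitivity`, `simulate`, `simstudy` (see `riaftbart --help`); every
stochastic command requires `--seed` and writes a manifest recording its
configuration.

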