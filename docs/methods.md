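# Methods

## The model

`riaftbart` fits a random-intercept accelerated failure time (AFT) model for
right-censored survival outcomes observed in K clusters (hospitals,
registries, trial sites) under J >= 2 treatment arms:

    log T_ik = f(A_ik, X_ik) + b_k + eps_ik,
    b_k ~ N(0, alpha * tau^2),    eps_ik ~ N(0, sigma^2),

where T_ik is the failure time in months of subject i in cluster k, A_ik the
treatment, X_ik pre-treatment covariates, and b_k a cluster-specific shift on
the log-time scale.  The regression function f is a sum of H regularized
regression trees (BART), so arbitrary nonlinearities and treatment-covariate
interactions are captured without pre-specification; the treatment enters the
forest as one more (categorical) predictor via indicator columns.  `alpha` is
a redundant multiplicative scale on the intercept variance (parameter
expansion) whose only purpose is to improve MCMC mixing of tau^2.

Assumptions: consistency, weak unconfoundedness given (X, V), positivity, and
covariate-dependent censoring; normality of residuals and intercepts.  The
model is deliberately an AFT rather than a proportional-hazards model: effects
are multiplicative on expected lifetime, which makes both the causal
contrasts and the sensitivity analysis directly interpretable, and the
simulations (below) probe robustness to non-normal residuals.

## Priors, centering, initialization

Responses are centered by an intercept-only censored-lognormal ML fit
(`mu_hat`, `sigma_hat`): y_cent = y * exp(-mu_hat).  Leaf values get the
prior N(0, xi^2 / (4 H k^2)) with xi = 4 sigma_hat, which induces
f ~ N(0, 4 sigma_hat^2 / k^2); the default k = 2 places ~95% prior mass on
[-2 sigma_hat, 2 sigma_hat].  Tree structures follow the standard branching
prior P(split at depth d) = 0.95 (1+d)^-2.  sigma^2 has an IG(nu/2,
nu*lambda/2) prior with nu = 3 and lambda solved in closed form so that
P(sigma < sigma^(0)) = 0.9, where sigma^(0) is the SD of the pooled residuals
of a parametric lognormal AFT with linear covariates; the same fit's
within-cluster mean residuals initialize b.  tau^2 and alpha carry IG(1, 1)
priors and start at 1.

## Sampling

One Metropolis-within-Gibbs iteration:

1. **Censoring augmentation.** For each censored subject, the latent centered
   log time z is drawn from N(f + b_k, sigma^2) truncated to (log y_cent,
   inf).  Truncated-normal draws use inverse-CDF sampling in the body and an
   exponential-rejection tail sampler beyond 5 SDs.
2. **Forest sweep.** Bayesian backfitting over the H trees with partial
   response z - b: each tree proposes grow / prune / change with
   probabilities 0.25 / 0.25 / 0.50 (the classic move set minus swap, omitted
   for simplicity), accepted by Metropolis-Hastings with the leaf values
   marginalized out; leaf values are then redrawn from their conjugate normal
   conditionals.  Split values are drawn uniformly from the observed unique
   values of the chosen covariate within the node, excluding the node
   maximum, so both children are non-empty by construction (an exact
   equivalent of auto-rejecting empty-child proposals).
3. **Variance.** sigma^2 ~ IG((nu+N)/2, (nu lambda + sum r^2)/2) on the
   residuals z - f - b.
4. **Intercepts.** b_k ~ N(w S_k / (n_k w + sigma^2), sigma^2 w / (n_k w +
   sigma^2)), w = alpha tau^2, S_k the within-cluster residual sum.
5. **Parameter expansion.** alpha ~ IG(K/2 + 1, 1 + sum b_k^2 / (2 tau^2)).
   This is the conjugate conditional under the IG(1,1) prior; it is the
   unique inverse-gamma shape for which the joint Gibbs chain leaves the
   prior invariant, which we verify by Geweke-style successive-conditional
   simulation in the test suite.  alpha is a single shared scalar: the scale
   parameters of both variance conditionals pool sum b_k^2 over clusters,
   which is only coherent for a shared alpha.
6. **Intercept variance.** tau^2 ~ IG(K/2 + 1, sum b_k^2/(2 alpha) + 1).

Defaults: H = 200 trees, 1000 burn-in + 3500 stored draws, thin 1.  mu_hat is
added back to all stored draws of f, so posterior f values are absolute
log-months.  All randomness flows through one seeded `numpy` Generator; a
fixed seed reproduces a chain bit for bit.

## Causal contrasts

Counterfactual predictions f_d(a, x_i) are stored for every arm at every
training row.  The pairwise CATE on the log-time scale is the per-draw
average of f_d(a_j, x_i) - f_d(a_j', x_i) over all N subjects (the cluster
intercepts cancel); CATT averages over the reference arm's subjects only.
The per-draw averages form the posterior of the effect; intervals are
equal-tailed 2.5%/97.5% quantiles.  The averaging weight is 1/N, the
empirical distribution of (X, V) (with equal cluster sizes this coincides
with the 1/(n_k K) convention).

Survival-scale summaries use the subject-level lognormal survival function
S(t) = 1 - Phi((log t - f - b_k)/sigma) evaluated per posterior draw.
Contrasts at a horizon t* (default 60 months, the 5-year horizon) are formed
per subject — each subject's own cluster intercept enters both arms — and
averaged; RMST (area under S up to t*) uses the closed-form lognormal partial
expectation, with a trapezoid integrator provided for arbitrary curves and
tested against it.  For subjects outside the observed clusters the intercept
is marginalized by drawing a fresh b ~ N(0, alpha_d tau2_d) per draw.  The
subject-level contrast convention (rather than contrasting group-averaged
curves) matches the CATE definition; both reduce to the same quantity on the
log-time scale.

## Sensitivity analysis for unmeasured confounding

The confounding function c(a_j, a_m, x, v) is the difference in mean
potential log survival under a_j between subjects observed under a_j and
those observed under a_m at the same covariates; it is zero for every
ordered pair exactly under weak unconfoundedness.  Given posited signs and
bounds, the bias of the naive CATE has the closed form implemented in
`bias_formula`, and it is removed by shifting each subject's observed log
time by the GPS-weighted sum of confounding values and refitting.  The shift
is applied to the observed time whether censored or not, which moves the
truncation threshold of the augmentation coherently.

Uncertainty propagates by nested multiple imputation: Q1 draws of the
generalized propensity scores (default: fixed-effects multinomial-logistic
model with nonparametric-bootstrap refits; a flexible classifier can be
plugged in as a callable) crossed with Q2 uniform draws of the confounding
functions, bounded by +/- omega * sigma_hat where sigma_hat is the residual
SD from an initial unadjusted fit.  The Q1 x Q2 posterior samples are pooled;
we report the pooled mean, equal-tailed interval, and a between/within
variance decomposition.  Confounding functions are constants in (x, v) per
draw.  Inner fits run shortened chains (250 + 500 by default) with
deterministic child seeds; failures are tolerated up to 10%.

The bias identity behind the correction is exact when c is known and the GPS
is exact; the illustrative experiment in the test suite (one measured + one
unmeasured binary confounder, known c averaged over x) confirms the adjusted
estimator tracks the oracle analysis that observes the confounder.

Cluster-level unmeasured confounding is deliberately not a target of the
correction: the random intercepts absorb cluster-constant confounders (also
verified empirically in the tests).

## Simulation engine

The shipped design mimics a national cancer-registry setting: K = 20
clusters of n_k = 500; ten confounders (5 standard normal, two 3-level
categoricals with probabilities 0.3/0.3/0.4, Bernoulli 0.6/0.4/0.5);
treatment among three arms from a random-intercept multinomial logit
(tau_k ~ N(0,1)) with intercepts calibrated by stochastic fixed-point
iteration to a 6:3:1 allocation; Weibull counterfactual times

    T(a_j) = [-log U / (lambda_j exp(beta0_j + X betaL_j + G betaNL_j + b_k))]^(1/eta)

with lambda = (3000, 1200, 2000), b_k ~ N(0, 4^2), eta = 2 (proportional
hazards) or exp(0.7 + 0.5 x1) (non-proportional, evaluated per subject and
applied to all of that subject's arms), and exponential censoring calibrated
by bisection to a 10% or 40% censored fraction.  A lognormal-residual
variant (matched residual SD pi/(sqrt 6 eta)) is available as a benchmark in
which the fitted model is exactly correct.

Choices worth knowing:

- **Stand-in coefficients.** The linear and nonlinear coefficient vectors
  (and the G basis: x1^2, x2^2, x1*x3, x4*1{x8=1}) are documented stand-ins
  of moderate magnitude, distinct per arm so the three response surfaces are
  non-parallel; all are config-overridable.  The per-arm intercepts beta0
  place arm-level median survival at roughly 90/65/75 months so that the
  5-year horizon is clinically meaningful and the RMST contrasts are on the
  month scale; without them, unit-scale coefficients against rates of
  thousands put median survival below one month.
- **Independent uniforms.** U is drawn independently per (subject, arm);
  averaged contrasts are identical under shared or independent draws, and
  independent draws avoid artificial rank coupling.  `shared_u=True`
  restores the single-U reading.
- **Cluster scales.** tau_k ~ N(0, 1^2) and b_k ~ N(0, 4^2) follow the
  (mean, SD^2) reading; b's SD of 4 means cluster medians span roughly
  e^{+/-4} months around the design median, a very strong institution
  effect.  Both are configurable.
- **Ground truth.** `true_cate` integrates the closed-form Weibull survival
  (or its incomplete-gamma RMST) over fresh Monte-Carlo covariates and
  cluster draws — no event-simulation noise.  The study harness scores each
  replicate against its own sample-conditional truth (same closed forms
  evaluated at the replicate's realized covariates and cluster effects) by
  default, because the CATE estimand conditions on the realized (X, V); a
  fixed population truth is available via `truth="population"`.
- **Censoring calibration** solves mean(1 - exp(-r T)) = target by bisection
  on the pilot times, which is deterministic and monotone in r — no
  Monte-Carlo noise enters the root-finding.  Because the cluster SD of 4
  moves any finite cluster set's censored fraction by several points,
  percent-level calibration checks use population draws (a fresh cluster
  effect per subject).

## What the synthetic experiments do and do not show

The generator reproduces the structural features the model targets —
clustered assignment and outcomes, confounding through shared covariates,
non-proportional hazards, non-normal (extreme-value) residuals, heavy
right-censoring — under known truth, so the tests demonstrate calibration of
the sampler's conditionals (exact, via successive-conditional simulation),
parameter recovery, near-nominal frequentist coverage of RMST contrasts, and
bias removal by the confounding correction when c is known.  They do not
emulate informative censoring, covariate measurement error, missing data,
interference between subjects, or time-varying treatments; performance on
real registry data additionally depends on positivity and on unmeasured
confounding, which is exactly what the sensitivity analysis is for.

## Desk-scale validation sizes

The validation suite runs reduced problem sizes chosen as this package's
desk-scale defaults: conditional-correctness on K=2, n=20 with 3000
independent short chains; parameter recovery at K=20, n_k=50 (one full-length
check plus 20 reduced-chain seeds); coverage on K=10 clusters of 100 with 60
replicates, 50 trees and 200+400 chains; the illustrative sensitivity
experiment with 20 replicates of n=400 and three analyses each.  The
acceptance script's censoring targets use a 100,000-subject calibration
pilot and a fresh 10,000-subject evaluation sample.

## Known limitations

- No random slopes, cluster-level covariates, or nonparametric residual /
  intercept priors; no common-support trimming.
- The GPS default is a parametric multinomial logit; severe misspecification
  of treatment assignment propagates into the sensitivity correction (plug
  in a flexible classifier where that is a concern).
- Posterior prediction at covariate points far from training data inherits
  BART's flat extrapolation.
- Left truncation, interval censoring, competing risks and time-varying
  covariates are out of scope.
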