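# Methods

This document records the statistical models, assumptions, default
parameters and numerical choices behind `einvpolicy`, plus known
limitations. Every quantitative statement here is computed by the test
suite (`tests/`) or by `scripts/acceptance.py`; nothing is quoted from
external sources.

## Setting

Each record is `(y, x, t, env, prop)`: outcome, covariates, binary
treatment, environment label, and the probability with which the logging
policy chose the *logged* action given `x`. Within an environment,
treatment assignment depends on covariates only through the logging policy
(no unobserved confounding of `T` given `X`), while a latent `U` may
confound `X` and `Y`. The conditional average treatment effect (CATE) is
`tau_e(x) = E[Y | X=x, T=1, env=e] - E[Y | X=x, T=0, env=e]`.

A subset `S` of covariates is *effect-invariant* (e-invariant) when
`E[tau_e(X) | X_S = x_S, env=e]` is the same function of `x_S` for every
environment. The package tests this hypothesis subset-by-subset and builds
policies on accepted subsets.

## Wald test (`wald_einv_test`)

Model: response linear in covariates with environment-specific main effects
and a CATE linear in `(1, x_S)` with environment-interaction coefficients
`B_e`. Records are reweighted by `w_i = pi_ref(t_i | x_{S,i}) / prop_i`
(reference policy: Bernoulli(1/2) by default) and the treatment is centered
as `c_i = t_i - pi_ref(1 | x_{S,i})`, which makes the CATE block orthogonal
to main-effect misspecification. The estimating equations reduce to
weighted least squares; the null `B_e = 0` for all non-reference
environments is tested with `T = n vec(B)' V^+ vec(B)` against a
chi-squared with `(l-1)(1+|S|)` degrees of freedom.

Numerical choices:

* QR with column pivoting for the rank check, so rank deficiency reports
  the offending columns.
* Sandwich covariance `J^{-1} Omega J^{-T}` with an HC3-style leverage
  rescaling of the moment contributions (`1 / clip(1 - h_i, 0.05, ·)`).
  The policy-ratio weights are heavy-tailed under logistic logging, and the
  plain sandwich materially underestimates the variance at n in the low
  thousands; the rescaling was calibrated on a clean Bernoulli-logged
  design where the plain sandwich is already correct
  (`tests/test_wald.py`, `tests/test_acceptance.py`).

Assumptions: linear CATE in `(1, x_S)` per environment. When the true CATE
is nonlinear (cubic in the generator's `nonlinear_cate` variant), the test
over-rejects the truly invariant subset; this violation, and the DR test's
robustness to it, are measured in
`tests/test_acceptance.py::test_wald_level_violation_with_cubic_cate_while_dr_holds`.

## DR test (`dr_einv_test`)

Algorithm: split the sample 50/50 (stratified by environment x arm), fit
per-environment, per-arm outcome regressions on the first half (default: a
random forest with 50 trees and minimum leaf size 10), and form doubly
robust pseudo-outcomes on the second half:

```
o = mu1(x) - mu0(x) + 1{t=1}(y - mu1(x))/pi - 1{t=0}(y - mu0(x))/(1 - pi)
```

with `pi` the known logging propensity of treatment. With known `pi`,
`E[o | x, env]` equals the CATE for *any* fixed outcome models (one-sided
double robustness); with correct outcome models the same holds for any
`pi`. Both directions are verified at Monte-Carlo tolerance in
`tests/test_acceptance.py::test_pseudo_outcome_double_robustness_both_directions`.

Equality of `E[o | x_S]` across environments is then tested with a
multi-environment weighted residual-product (generalised covariance
measure) statistic: residualize `o` on `x_S` (pooled, 2-fold cross-fitted
cubic-polynomial ridge) and each reference-coded environment indicator on
`x_S` (2-fold cross-fitted cubic-polynomial *logistic classifier*), form
per-contrast products, and compare the normalized product means to
chi-squared with `l - 1` degrees of freedom.

Numerical choices, each adopted from explicit diagnostics (see the level
and power measurements in `tests/test_dr.py` and
`tests/test_acceptance.py`):

* **Classifier, not regressor, for the indicator residualization.**
  Unbounded regressors extrapolate outside `[0, 1]` in the covariate
  tails — exactly where the pseudo-outcome noise is heaviest — and inflate
  the level.
* **Direction weights on by default** (`DRTestConfig.direction_weight`).
  The plain product mean has provably vanishing power against slope-type
  alternatives when the gap `E[o | x_S, e] - E[o | x_S, ref]` is an odd
  function and the covariate distribution is symmetric: the integrand is
  odd and integrates to zero. The test therefore weights each contrast's
  products by the *sign* of the estimated gap. The direction is derived
  entirely from the nuisance half: the fitted per-environment outcome
  models imply an effect `mu_e(x,1) - mu_e(x,0)`, whose polynomial
  projection onto `x_S` is fitted on the nuisance half and evaluated on the
  test half. Because the weight is a function of `x_S` and of the
  independent half only, the weighted products keep a zero conditional mean
  under the null, and the chi-squared reference with `l - 1` degrees of
  freedom is unchanged. (An earlier variant that estimated the direction on
  the test half's own folds aligned the weight with the second-order
  residualization bias and inflated the level; see the unit test
  `test_direction_weight_restores_power_on_odd_gap` for the power
  mechanism.)
* Covariance of the product vector estimated empirically; pseudo-inverse
  quadratic form.

## Zero-shot policy learning (`learn_einv_policy`)

Lasso screening of covariates against cross-fitted pseudo-outcomes (cap:
10), exhaustive subset enumeration including the empty set, per-subset
e-invariance test (Wald or DR), pooled CATE fit on accepted subsets, argmax
policy, and selection of the subset maximizing the average predicted effect
of its own policy on the test environment's covariates. If nothing is
accepted, the constant policy maximizing the pooled average effect is
returned and flagged. The dominance guarantee — the learned policy's value
is at least every constant policy's value in any test environment — is
checked across 20 seeded test environments in
`tests/test_acceptance.py::test_einv_policy_dominates_constant_policies`.

`pooled_cate_fit` uses 2-fold cross-fitting: each record's pseudo-outcome
is built from the other half's nuisances, and a single regression (ordinary
least squares by default) is fit on all records.

## Few-shot estimation (`few_shot_fit`)

Assumes a separable test-environment CATE `tau(x) = f(x_S) + g(x_N)` whose
`x_S`-conditional mean must match the training CATE. With a linear class
for `g` and a linear projector `q(x_S) = E[x_N | x_S]` (refit on the test
covariates), the constrained least-squares problem reduces to ordinary
least squares of `o - tau_tr(x_S)` on the centered regressors
`x_N - q(x_S)`, so only `|N|` parameters are learned from the small test
sample. Efficiency against an unconstrained DR fit and slope recovery are
measured in
`tests/test_acceptance.py::test_few_shot_constraint_improves_small_sample_fit`.

## Simulators and generator realism

* `simulate_intro`: one covariate, latent confounder `U`, environments
  scale the `U -> X` edge and shift the outcome; CATE `1 + x` in every
  environment. Treatment by a probit-style rule in `1 + x`, so propensities
  approach 0/1 in the tails — deliberately kept, as it reflects logging
  policies that rarely explore.
* `simulate_example1`: three covariates, two latents; `x1` and `x3` load on
  the latent `U1` with environment-specific coefficients `gamma1, gamma3`,
  `x2` on `U2` via `gamma2`; outcome shift `mu_e`. The CATE given `x2` is
  `1 + 0.5 x2` in every environment, while the CATE given `x1` has slope
  `0.5 gamma1 / (1 + gamma1^2)` — environment-dependent in general, so only
  `{x2}` is e-invariant. Variants: `linear`, `nonlinear_main` (nonlinear
  main effect), `nonlinear_cate` (cubic effect). Logging policy: logistic
  in all three covariates. Note `gamma / (1 + gamma^2)` is not injective:
  some parameter pairs make `{x1}` *accidentally* near-invariant, which
  matters when choosing alternatives for power studies.
* `simulate_mrt_fixture`: a micro-randomized-trial-style fixture with users
  as environments, Bernoulli(0.6) randomization, a small set of effect
  moderators with shared (invariant) coefficients and a user-specific
  engagement effect.

## Limitations

* **Heavy-tailed inverse-propensity weights.** With logistic or probit
  logging, `1/pi` can have infinite higher moments (for the intro SCM,
  `E[1/pi]` itself diverges). Consequences, all reproduced by the test
  suite or the acceptance script rather than asserted abstractly:
  * The DR test's chi-squared approximation fails for environment
    parameters with `|gamma1| >~ 2` (logging-index standard deviation
    around 3) at n = 2000: the residual products then have effectively
    nonexistent third/fourth moments and the product-mean CLT has not set
    in. Diagnostics with *oracle* residualizations show the same
    inflation, so no nuisance-estimation improvement can repair it, and
    neither could multiplier bootstrap, median-of-means, variance
    weighting, or propensity clipping in our experiments.
    `scripts/acceptance.py --seed 1` lands on such a draw
    (`gamma1 = -2.96`) and reports t2 = 14.5%, outside the nominal band,
    while the fixed draw used by
    `tests/test_acceptance.py::test_dr_test_holds_level` is moderate and
    passes. Treat DR p-values with caution whenever logged propensities
    reach below ~1e-3.
  * The Wald test's leverage-corrected sandwich keeps only approximate
    level at ~1000 records per environment under such draws:
    `tests/test_acceptance.py::test_wald_test_holds_level` measured 0.072
    against the nominal band [0.030, 0.070] (binomial SE 0.0097) at its
    pre-registered seed, and this deliberately remains a failing test
    rather than a re-tuned passing one.
  * `pooled_cate_fit` has heavy-tailed error under near-deterministic
    logging: oracle recovery on the intro SCM is well within tolerance at
    the pre-registered acceptance seed, but occasional seeds give several
    times the typical error. No propensity clipping is applied; positivity
    below 1e-6 raises an error instead.
* **Wald power threshold.** At the acceptance configuration (hand-picked
  clear-gap parameters, total n = 8000), measured Wald power for the
  non-invariant singleton was 0.86 (SE 0.024) against the 0.9 criterion:
  monotone in n, but below the target — also left red rather than re-tuned,
  since raising the alternative's strength after observing the result would
  invalidate the measurement.
* The DR test's direction weight targets slope-type gaps; alternatives
  whose gap has constant sign are detected by the unweighted products as
  well, but adversarial gaps orthogonal to the learned direction reduce
  power toward the plain test's.
* Multi-level treatments are handled by reduction to pairwise
  binary contrasts only; the Wald test rejects them outright.
* Policy evaluation by residual bootstrap assumes the per-environment
  linear outcome model is adequate; model inadequacy is surfaced by rank
  and residual diagnostics, not corrected.
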