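# Methods

`mistrat` is a simulation laboratory for a focused question in
missing-data methodology: when the average causal effect (ACE) of a binary
exposure on a continuous outcome is estimated by outcome regression, should
multiple imputation (MI) be carried out separately within each exposure
group? This note documents the data-generating models, the missingness
mechanisms, the imputation engine, the estimators and performance metrics,
the numerical choices, and the limits of what the simulations can show.

## Target analysis and estimand

The analysis model is the no-interaction linear outcome regression

    E[Y | X, C] = t0 + t1 X + t2 C1 + t3 C2 + t4 C3 + t5 C4 + t6 C5,

fitted by ordinary least squares. Under exchangeability given the
confounders C = (C1, ..., C5), consistency, positivity and no effect
modification, the exposure coefficient t1 equals the ACE
E[Y^(x=1)] − E[Y^(x=0)]. The simulations deliberately violate the
no-effect-modification assumption to a controlled degree (below), so the
analysis model is misspecified in most scenarios; the target value of t1 is
fixed at 0.3 throughout by calibration.

## Complete-data generation

Each record is generated sequentially, emulating a cohort of adolescent
participants with an exposure (e.g. frequent substance use), five binary
confounders, a continuous standardized mental-health outcome and one
standardized continuous auxiliary variable used only for imputation:

1. `A ~ N(0, 1)` (auxiliary; think "age at entry", standardized);
2. `C1 ~ Bernoulli(0.375)`;
3. `C2 .. C5` each Bernoulli with a logistic-linear probability in all
   previously generated variables;
4. `X ~ Bernoulli(expit(b0 + b'(A, C1..C5)))`, the exposure;
5. `Y = a0 + a1 C1 + ... + a5 C5 + a6 X + delta * a6 * X * C5 + eps`,
   `eps ~ N(0, sigma_y^2)`.

`delta` in {0, ±0.25, ±0.5, ±0.75} scales an exposure-by-C5 interaction
(none / weak / moderate / strong, both signs); because both exposure terms
carry `a6`, the large-sample coefficient of X in the no-interaction
analysis model is exactly linear in `a6` at fixed `delta`.

**Default coefficients.** The per-variable slopes are package defaults
chosen so that (a) the marginal prevalences of C1–C5 sit near 37.5%, 21.7%,
10.5%, 36.3% and 58.8%, matching the motivating cohort's descriptive
statistics, and (b) the exposure is most strongly associated with C4 and
the "strong" confounder C5, more weakly with C2/C3, and only weakly with A
and C1, reproducing the direction and rough strength of the cohort's
exposed-vs-unexposed contrasts. All coefficients are plain fields of
`GenerationConfig`, so users with access to a real cohort can substitute
their own estimates. Absolute bias magnitudes reported by the package
depend on this coefficient set; the qualitative contrasts between methods
do not.

**Calibrated quantities.**

* Confounder intercepts (C2–C5) were fixed once, by root-finding on the
  expected marginal prevalence at n = 10^6, and shipped as constants.
* The exposure intercept is calibrated per prevalence scenario (10%, 30%,
  50%) by Brent root-finding on the *expected* prevalence — the average of
  each record's logistic probability over one large covariate draw — which
  is a deterministic, lower-variance version of redrawing X at every
  candidate intercept. Tolerance: ±0.002 in prevalence at n = 10^6.
* The main effect `a6` is calibrated per (prevalence, delta) by fitting the
  analysis model once to a large noiseless dataset generated with `a6 = 1`
  and scaling: `a6 = 0.3 / c` where `c` is the fitted X coefficient. This
  exploits the exact linearity noted above.
* `sigma_y = 1.125` was fixed once so that the complete-data analysis at
  (n = 700, 30% prevalence) has ≈80% power for t1 = 0.3 at the 5% level,
  which makes coverage comparisons meaningful across prevalence scenarios
  (sample sizes 1300 / 700 / 550 at 10 / 30 / 50% prevalence were chosen
  for approximately equal standard errors).
* Calibration uses a dedicated seed, independent of replicate seeds, so
  scenario parameters are constants across replicates.

## Missingness mechanisms

Two structures; in both, A, C1–C3 and X are always fully observed.

*Outcome only*: `logit P(M_Y=1) = b0 + 0.030 A + log(3) X + b1 C5 + b2 X C5`,
calibrated to 30% missing.

*Outcome and confounders*: indicators drawn sequentially,

    logit P(M_C4=1) = g0 + 0.323 A − 0.624 X
    logit P(M_C5=1) = z0 − 0.029 A + 3.835 M_C4 + log(3) X + z1 C5 + z2 X C5
    logit P(M_Y =1) = e0 − 0.025 A + 0.685 M_C4 + 0.658 M_C5 + log(3) X
                      + e1 C5 + e2 X C5

calibrated to 10% / 10% / 20% marginal missingness; the large M_C4
coefficient in the C5 model controls the overlap of missingness between the
two confounders, and ≈30% of records end up with at least one missing
value.

Scenarios set the C5-linked slopes: (i) zero (missingness depends on
exposure only); (ii) C5 slope log(3); (iii) additionally an X-by-C5 slope
log(2). Intercepts are calibrated per (prevalence, structure, scenario) by
sequential Brent root-finding on expected proportions, marginalising
analytically over the earlier indicators; `delta` does not enter any
missingness model, so no per-delta recalibration is needed. In scenarios
(ii)/(iii) of the multivariable structure the C5 model conditions on the
underlying value of C5 itself; the mechanism is implemented exactly as
written, without reinterpretation.

## The chained-equations engine

A from-scratch fully-conditional-specification (MICE-style) imputer:

* **Continuous targets** (Y): proper Bayesian linear regression — least
  squares on rows where the target is observed, residual variance drawn
  from its scaled inverse-chi-square posterior, coefficients from the
  conditional Gaussian posterior, imputations from the predictive normal.
* **Binary targets** (C4, C5): maximum-likelihood logistic regression via
  ridge-stabilised Newton-Raphson; coefficients drawn from the asymptotic
  Gaussian approximation (mean = MLE, covariance = inverse observed
  information), imputations Bernoulli at the implied probability. The
  asymptotic draw is the classical chained-equations default. On detected
  separation, perfect prediction or non-convergence, the fit is repeated
  with a fixed ridge penalty (1.0 on standardised predictors); the tiny
  always-on ridge (1e-6) only guards conditioning.
* **Predictor sets**: all analysis variables plus A, excluding the target;
  method-specific interaction terms (see below) are included unless they
  contain the target, and are recomputed from the current imputations at
  every refit (passive recomputation — products are never stale).
* **Cycling**: masked cells are initialised by resampling observed values;
  variables are then updated in the order C4, C5, Y for 5 cycles per
  imputed dataset (m = 30 by default; scaled-down runs use m = 10). When a
  single variable is incomplete, its model is refitted on identical rows
  every cycle, so the engine fits once and draws m times — an exact
  shortcut, not an approximation.
* **Stratified mode** (MI-EG): the whole procedure runs independently
  inside X = 0 and X = 1 (X and all X-interactions drop out as constants),
  and the j-th imputed subsets are concatenated into the j-th completed
  dataset. Strata that cannot support the models raise a distinct
  degenerate-stratum error which the runner records as a per-replicate
  failure rather than aborting the cell. For full-scale MI-EG runs the
  imputation count follows the percentage-of-incomplete-records rule of
  thumb, never below 30, equal across strata so subsets pair 1:1.

Methods: CCA (complete-case analysis) plus six MI variants — MI-NI (no
interactions), MI-ExO (X*Y), MI-ExC (X*C5), MI-ExOC (both), MI-ExI (X by
every incomplete variable), MI-EG (stratified). With outcome-only
missingness MI-ExO collapses to MI-NI and MI-ExOC to MI-ExC at the
predictor-set level, so those cells run four methods only.

## Estimation, pooling, metrics

Each completed dataset gets the OLS analysis fit (df = n − 7; A never
enters). MI estimates are pooled by Rubin's rules with Barnard-Rubin
small-sample degrees of freedom (the classical large-sample df is a
config switch); analysis sample sizes of 500–2750 make the small-sample
adjustment the sensible default. 95% intervals use the t reference.

Per (scenario × method) cell, over the successful replicates: mean
estimate, bias (absolute and relative to 0.3), MSE = bias² + sample
variance (n−1 divisor; consequently MSE = bias² + EmpSE² exactly), EmpSE,
ModSE (mean model-based SE), coverage of the true 0.3, and Monte-Carlo
standard errors (EmpSE/√n for the mean, EmpSE/√(2(n−1)) for EmpSE,
binomial for coverage). Failed replicates are excluded and counted.

## Seeding and reproducibility

A counter-based scheme: the stream for each (cell, replicate) is derived
from the master seed and the cell's identifiers via `SeedSequence`, then
split into data-generation, missingness, and one substream per method;
inside the imputer each imputation stream (and stratum) gets its own
child stream. Results are therefore bit-identical across reruns and
independent of execution order or worker count; all methods within a
replicate see the identical incomplete dataset (common random numbers),
which sharpens method contrasts and is verified by hashing.

## Problem sizes and Monte-Carlo allowances

The full study design is 252 cells × 2000 replicates × m = 30. The bundled
tests and the acceptance script run scaled-down versions: 250–500
replicates per cell for bias grids (1000–1500 for single-cell SE and
coverage checks), m = 10, 5 cycles, calibration at n = 10^6. At these sizes
the Monte-Carlo standard error of a relative-bias estimate is roughly
1.3–3% (of the true effect), so every fixed bias band asserted by the test
suite is widened by three Monte-Carlo standard errors of the quantity under
test. This allowance is a property of the scaled-down design, fixed in
advance; it shrinks automatically if replicate counts are raised.

## What the generator does and does not emulate

It reproduces the cohort's variable roles, marginal prevalences,
direction/strength of exposure-confounder associations, missingness rates
and overlap structure. It does not model the longitudinal wave structure,
continuous confounders, missingness in A or X, or the cohort's exact
(unpublished) generation coefficients — so absolute bias magnitudes (e.g.
the worst-case bias of MI-NI under strong negative interaction) are
specific to the default coefficient set, while unbiasedness results, sign
patterns, SE calibration and coverage conclusions are structural and
transfer. MNAR mechanisms, predictive mean matching, joint multivariate
normal imputation and substantive-model-compatible FCS are out of scope.

## Known limitations

* The asymptotic-Gaussian logistic draw is improper (not a full Bayesian
  posterior draw); with the sample sizes used here the difference from a
  bootstrap or data-augmentation draw is negligible, but it is a choice.
* In multivariable scenarios (ii)/(iii) the C5 missingness model depends on
  C5's own underlying value (self-masking); the mechanism is implemented
  verbatim, and the MAR label for those scenarios should be read in the
  study's operational sense.
* MI-ExI's interaction set is defined over the variables actually masked in
  a given dataset; in outcome-only cells this would reduce it to MI-NI
  rather than MI-ExC, which is one reason those cells run the four-method
  panel only.
* The ridge fallback slightly shrinks coefficient draws in separated
  strata; this is exactly the regime (tiny exposed groups) where MI-EG is
  expected to degrade, and the degradation is visible in the results as
  intended.
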