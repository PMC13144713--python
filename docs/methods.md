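# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `hardship_ddm`.  The package reimplements, end to end,
an analysis pipeline linking childhood material hardship to adolescent
evidence-accumulation efficiency and attentional problems: per-subject
diffusion-decision-model (DDM) decomposition of a 100-trial two-choice
task, a simulation-recovery validation, a fixed-loading latent growth
curve of hardship across ages 1-9, covariate-adjusted standardized
regressions, and a percentile-bootstrap indirect effect.  Because the
cohort data it emulates are access-restricted, all empirical exercises run
on a calibrated synthetic cohort; what that does and does not demonstrate
is discussed at the end.

## Diffusion decision model

A two-choice decision is modelled as a Wiener process with drift `v`
between absorbing boundaries 0 and `a` (diffusion coefficient fixed at 1;
one scale constraint is mandatory and s = 1 matches the convention under
which the cohort estimates `v ~ 2.9`, `a ~ 1.4` live).  Accuracy coding is
used throughout: the upper boundary is the correct response, the relative
start `z in (0, 1)` is the fraction of `a` at which evidence accumulation
begins, and observed RT = decision time + non-decision time `t0`.
Across-trial variabilities follow the standard full DDM: drift is
`Normal(v, sv^2)` per trial, the start point `Uniform(z +/- sz/2)`, the
non-decision time `Uniform(t0 +/- st0/2)`.

### First-passage density

The likelihood kernel is the first-passage-time density evaluated with the
dual-series representation: a small-time and a large-time expansion of the
drift-free scaled density, with the number of terms chosen adaptively for
an absolute truncation error of 1e-7 per evaluation and the branch picked
by whichever needs fewer terms.  Drift variability is marginalised
analytically (a Gaussian integral); start-point and non-decision-time
variability are marginalised with an 11-node Gauss-Legendre rule each
(their integrands are smooth and compactly supported, so fixed-node
quadrature keeps the likelihood deterministic for the samplers).  The test
suite verifies normalization to 1e-6 over the cohort parameter range,
agreement of the two series branches to 1e-6 on their overlap, and
bin-level agreement with the simulator under all variabilities.

### Simulator

Trials are simulated by Euler-Maruyama with a 0.1 ms step.  Naive
discrete boundary checking overestimates first-passage times by
O(sqrt(dt)); between consecutive points we therefore sample the Brownian-
bridge crossing event (probability `exp(-2 d0 d1 / dt)` for boundary
distances d0, d1), which removes the leading-order bias.  With the
correction, simulated choice proportions and mean decision times agree
with the closed forms within Monte-Carlo error at 2e5 trials; without it
the mean decision time is biased by about +3 ms.  Responses landing after
the task deadline (1.75 s from stimulus onset) are recorded as omissions.

### Estimation

Per-subject Bayesian estimation samples the 7-parameter space with
adaptive-Metropolis chains: the proposal covariance is the running
posterior covariance scaled by 2.38^2/7 times a global factor tuned toward
~28% acceptance, adapted during warmup only (moment accumulators restart a
third of the way through warmup to drop the transient) and frozen for the
kept draws.  Defaults are 3 chains x 2,000 warmup + 2,000 kept; the
"reduced" profile used by the large simulation studies is 2 chains x 500
warmup + 1,000 kept.  Point estimates are posterior medians; central 95%
intervals, classic potential-scale-reduction R-hat (floored at 1, so
identical chains report exactly 1.0) and effective sample sizes are
attached.  Fits with any R-hat above 1.1 are rerun once with doubled
draws and flagged if still above; the reduced profile skips the
escalation (classic R-hat is noisy at 1,000 autocorrelated draws, so
escalation there mostly churns) and only flags.

Priors are independent and truncated to the parameter invariants:
`v ~ N(2.5, 2.0)`, `a ~ N(1.5, 1.0)`, `z ~ N(0.5, 0.15)`,
`t0 ~ N(0.3, 0.15)`, `sv ~ N(1.5, 1.0)`, `sz ~ N(0.15, 0.12)`,
`st0 ~ N(0.12, 0.10)` (units: evidence/s, evidence, fraction, seconds).
The variability priors are deliberately centred on plausible magnitudes
rather than at zero: zero-mode (half-normal) priors pile posterior mass on
the boundary when 100 trials say little about sv, and because the
likelihood carries a strong (v, sv) trade-off, that shrinkage propagates
into a ~-0.25 bias on drift itself.  Centring sv near the value implied by
the published cohort accuracy removes the bias at the cost of some prior
sensitivity (below).

### Identifiability: the (v, sv, sz) ridge

At the task's scale (about 100 trials, ~90% accuracy) the joint likelihood
has a long, nearly flat, *asymmetric* ridge: large `sv` and `sz` paired
with large `v` fit almost as well as the truth (a few log-likelihood units
even at 1,200 trials).  Consequences measured in this implementation and
reflected in the tests:

* unregularised (maximum-likelihood) point estimates drift upward along
  the ridge; consistency is asserted via likelihood-ratio confidence
  regions, not per-parameter distances;
* posterior medians remain prior-sensitive in the ridge directions even at
  1,000 trials (doubling prior SDs moves them by ~0.6-1.0 posterior SD),
  while `a` and `t0` are stable;
* simulation-recovery correlations at 100 trials/subject have information
  ceilings well below 1: roughly 0.85 for `v`, 0.8 for `a`, 0.65-0.7 for
  `z`, 0.95 for `t0`, and much lower for `sv`, `sz`, `st0` (`sz` is
  essentially unrecoverable from 100 trials).  More draws do not raise
  these numbers - they are posterior-width limits, and because correlation
  is invariant under the linear shrinkage that stronger priors induce,
  neither does shrinkage.  Reported recovery correlations of >= 0.90 for
  all four main parameters at this trial count are attainable, in our
  analysis, only by estimation schemes that pool across subjects
  (hierarchical shrinkage with data-dependent pooling); the per-subject
  estimator implemented here is honest about the ceiling.

## Trial preprocessing

Subjects are excluded when they completed fewer than 75 of 100 trials
(omission rate > 25%) or their accuracy is below 55%; both thresholds are
strict, and exclusion accuracy is computed over completed trials before
fast-guess removal (the alternative order is a flag).  Responded trials
with RT < 200 ms are then removed as fast guesses (strict; 200 ms exactly
is retained).  A completed trial is any trial with a response.  The filter
is idempotent and retained + excluded = input subjects by construction.

## Hardship growth curve

Eight binary hardship items per wave (ages 1, 3, 5, 9) are summed to wave
scores 0-8; cumulative hardship is the sum over observed waves (0-32).  A
wave with 6 or 7 observed items is rescaled to the 8-item metric; with
fewer it is set missing.  The latent growth curve model treats wave sums
as continuous:

    y_w = i + lambda_w * s + e_w,  lambda = (0, 2, 4, 6),
    (i, s) ~ N(mu, Psi),  e_w ~ N(0, sigma_e^2) iid.

Estimation is maximum likelihood on the implied 4-variate normal with
casewise (full-information) handling of missing waves, optimised by
L-BFGS-B over (mu, log-SDs, atanh correlation) from moment-based starts
with two perturbed restarts; latent-mean standard errors come from the
numeric observed information.  Residual variances are constrained equal
across waves, which makes the model exactly a random-intercept-random-
slope linear mixed model on complete data - the suite asserts equality of
the maximised log-likelihood with the statsmodels MixedLM oracle to 1e-4.
Near-zero variance solutions are flagged as boundary (Heywood) cases, not
errors.  Factor scores are empirical-Bayes posterior means (regression
method), so their variance is shrunk below the latent variance; the
score-truth correlation implied by the model closed form (~0.60 for the
slope at the default settings) is what the tests assert.

## Outcome models

*Attentional problems.*  A one-factor maximum-likelihood model with free
loadings and uniquenesses (factor variance fixed at 1) reduces the
five-indicator battery to regression-method factor scores, standardized to
mean 0 / SD 1.  For three indicators the ML solution equals the classic
closed form from the three covariances, which the tests exploit.

*Regressions.*  Tables report unstandardized `b`, standardized
`beta = b * sd(x)/sd(y)`, SE, z and p per predictor.  Complete data use
ordinary least squares via the normal equations (keeping the beta/
correlation identity exact to machine precision).  With missing data the
coefficients come from the maximum-likelihood multivariate-normal
mean/covariance estimated by EM (equal to OLS when nothing is missing);
their SEs come from a seeded case bootstrap.  Ethnoracial identity enters
as dummy codes with a configurable reference group (default: the largest
group).

*Indirect effects.*  The indirect effect of hardship (x) on attention (y)
through drift (m) is `a * b` with `a` from `m ~ x (+ covariates)` and `b`
the coefficient of m in `y ~ m + x (+ covariates)`; `c = c' + a*b` holds
exactly on complete data and is asserted at 1e-12.  Intervals are seeded
case-resampling percentile bootstrap (default 10,000 resamples, 95%
level); a bias-corrected variant is intentionally not the default.  With
no covariates the two path regressions reduce to closed forms in resample
moments and the bootstrap is fully vectorised.  Calibration: across 500
simulated datasets (n = 200, both standardized paths -0.2) the 95% CI
covers the true product in 92-98% of replicates.

## Synthetic cohort

The generator emulates the study structure: a birth cohort (default
n = 3,714) with hardship waves from the latent growth process above
(defaults: intercept mean 1.0 SD 0.8, slope mean 0.15 SD 0.1, correlation
0.3, so hardship rises with age), items drawn per wave from a logistic
link anchored so the expected 8-item sum tracks the wave propensity over
the realistic 1-2 range; 8% of waves are missing at random.  A random
subsample (default 187) completes the task: exactly 100 trials, 20 per
emotion label, half male/half female faces, 1.75 s deadline, simulated
from that subject's true DDM parameters.

Population DDM parameters use the published cohort descriptives for the
means and SDs of v (2.89/0.91), a (1.38/0.33), z (0.49/0.05) and
t0 (0.36/0.08), truncated to the invariants.  The variability populations
are not published; the within-subject drift-variability mean was set to
1.45 by solving for the value that makes the model-implied cohort mean
accuracy equal the published 0.90 at the published parameter distribution
(the implied mean RT, 0.62 s, then falls slightly below the published
0.67 s - matching both exactly is not possible within this family), with
SD 0.5; sz ~ 0.15/0.06 and st0 ~ 0.12/0.05 s are field-plausible choices
made once.  Parameter draws are rejection-sampled into the invariant
region; all randomness descends from one seed sequence with per-subject
simulator seeds split off by a documented rule.

Effects are calibrated in closed form: true drift is
`v = mean_v + r * sd_v * Z_h + sd_v * sqrt(1 - r^2) * eps` with `Z_h` the
z-scored true cumulative hardship and r = -0.17, so corr(v, hardship)
equals the target in expectation; the attention factor is
`f = beta * Z_v + sqrt(1 - beta^2) * eps` with beta = -0.15 and no direct
hardship path, so the marginal indirect effect is the product of the two
standardized paths (0.0255, i.e. 0.03 at two decimals) and the total
effect is weak - mirroring the analysis the pipeline is meant to
reproduce.  Covariates (sex, pubertal stage, ethnoracial identity, family
structure, violence exposure, social deprivation) are correlated with
hardship (r = 0.3 for the adversity composites) but conditionally
independent of drift given hardship, so adjusted and marginal calibrated
effects coincide in expectation.  Optional correlations among DDM
parameters are not modelled (independence default).

The truth table (latents, true parameters, true factor) is written next to
the observable CSVs but is never an input to an analysis stage; the suite
reruns every analysis stage with the truth file deleted.

## Pipeline

One JSON configuration drives generate -> preprocess -> fit -> recover ->
growth -> outcomes; every stage reads and writes CSV/JSON in the run
directory, inputs are validated before any stage executes, and stage seeds
derive from the master seed by fixed offsets, giving byte-identical
artifacts on rerun (asserted in the suite).  No artifact contains
timestamps.  The report summarises exclusions, estimates, recovery,
growth and mediation in the order of the analysis narrative.

## Problem sizes and scaled-down defaults

The package's own test and acceptance runs use sizes chosen to keep a
full check-out practical on one CPU while preserving each estimand:
50-set recovery and 100-subject point-estimate studies at the task's 100
trials with the reduced sampler profile; n = 5,000 cohorts for
calibration checks (SE of a correlation ~0.014); 1,000-resample
bootstraps where the estimand is a CI endpoint (the 10,000 default
remains for analysis use); simulator oracles at 1.5e4-3e5 trials with
3-MC-SE tolerances.  MLE oracles run at 1,200-2,000 trials.

## What the synthetic cohort does not show

The generator reproduces the study's *statistical structure* (growth
process, calibrated effect sizes, task design, measurement layering), not
real data: hardship items are conditionally independent given the wave
propensity, attrition is missing-at-random, accuracy heterogeneity is
smoother than the published SD (0.19) suggests, emotions do not modulate
parameters, and DDM parameters are mutually independent across subjects,
unlike the published correlations (e.g. r(a, t0) = 0.43).  Passing tests
therefore demonstrate that the estimators recover what this model family
can encode, under its assumptions - not that the substantive findings
would replicate in the restricted cohort data.
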