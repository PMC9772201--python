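# Methods

`memchoice` simulates and analyses a two-part behavioural paradigm that
asks whether the intrinsic memorability of choice options biases
value-based decisions. This note documents the generative model, the
estimators, the numerical choices, and what the synthetic cohorts do
and do not establish about real data.

## The generative model

### Items

Each of the `n_items` (default 138) stimuli carries three latent
traits:

* `theta_mem` — hit propensity on the logit scale, `N(0.4, 0.35)`;
* `phi_fa` — false-alarm propensity on the logit scale, `N(-2.0, 0.3)`;
* `mu_value` — population-mean subjective value on the 0–10 rating
  scale, constructed as `10 * Phi(z)` from a standard normal `z`.

Memorability and value are coupled through a Gaussian copula. Because
`corr(z_m, 10*Phi(z_v)) = rho * sqrt(3/pi)` for bivariate-normal
latents, the requested Pearson correlation (default 0.15, a small
positive association that is itself not significant at 138 items) is
achieved by pre-scaling the latent correlation by `sqrt(pi/3)`.

The location/scale defaults were set so the default recognition cohort
reproduces what continuous-recognition studies of everyday stimuli
typically report: per-item corrected recognition with a median near
0.5, a false-alarm rate near 0.1, and split-half consistency (mean
Spearman rho) near 0.3. With a larger `theta_scale` the items become
implausibly separable (consistency well above 0.5).

### Recognition responses

A recognition stream shows one item per trial. Each participant sees
29 targets (repeating after more than 60 intervening trials) and 109
fillers (half of which repeat after 1–7 trials, serving as attention
probes); with the default filler-repeat fraction of 0.5 a stream is
221 trials long (the stream length is an emergent quantity, reported
but not targeted). On a repeat the press probability is
`expit(alpha_p + theta_mem_i)`; on any first presentation it is
`expit(gamma_p + phi_fa_i)`, with participant effects `alpha_p,
gamma_p ~ N(0, 0.5)`. Stream construction is rejection sampling:
target (first, repeat) slot pairs are placed under the long-gap
constraint, then the short-gap filler repeats, then one-shot fillers;
a dead end restarts the attempt (cap 1000). A validator re-checks
every invariant and is run on generated fixtures in the test suite.

### Ratings and choices

Ratings are continuous slider values `clip(mu_value + N(0, 2), 0, 10)`
— clipped, not re-sampled, at the bounds. Choice trials pair items by
within-participant value rank: 69 *close* pairs of adjacent ranks and
69 *far* pairs at the unique disjoint half-split (rank k with rank
k + 69), so every item appears exactly twice. Sides are randomized;
rating ties in the ranking are broken uniformly at random under a
participant-scoped seed.

The logistic choice backend draws
`P(right) = expit(b0_p + bv_p * dValue + bm_p * dMem)` with per-subject
coefficients `b0_p ~ N(0, 0.3)`, `bv_p ~ N(log 3.6, 0.5)` and
`bm_p ~ N(beta_mem, sd)`; `beta_mem = 0` is the null world in which
memorability has no causal role. The value slope default `log 3.6`
produces a fitted odds ratio per z-unit of |dValue| near 3.6, the size
of the value effect the paradigm is designed around. RTs are lognormal
with log-mean falling by 0.04 per z-unit of |dValue| (per-subject
intercept SD 0.15 and slope SD 0.02, so the RT mixed model has a
non-degenerate random structure); RTs beyond the 3 s deadline become
no-response trials and are dropped before covariate analyses. The DDM
backend instead simulates first passages with
`v = v0 + v_val*dValue + v_mem*dMem (+ v_int*dValue*dMem)`.

All randomness flows from one root seed through named substreams
(items, streams, recognition, ratings, ranks, sides, choices, ...), so
identical configurations are bit-reproducible and any stage can be
regenerated alone.

## Estimators

### Corrected recognition and split-half consistency

An item's memorability is CR = hit rate − false-alarm rate over the
participants who saw it as a target; a "correct rejection" is a
no-press on *any* first presentation (target or filler), which
maximizes counts and matches standard usage. Participants with fewer
than 3 hits or 3 correct rejections are excluded.

Consistency: participants are split into random halves, per-half item
CR is computed, and the Spearman correlation over items is taken; the
reported statistic is the mean over (default) 1000 iterations. The
chance distribution replays the *entire* procedure on data whose item
labels have been independently scrambled within each participant —
one scramble per null draw, fresh halves per iteration. Absent item
signal, scores are exchangeable across items within a participant, so
the observed statistic is the identity member of an exact
randomization family and
`p = (1 + #{null >= observed}) / (n_null + 1)` is calibrated (verified
empirically: null p-values uniform by KS at alpha 0.01 over 200
replicates). A subtlety worth knowing: because the two half-means of
an item are exact mirror deviations around the realized full-sample
mean, a single finite cohort's mean rho fluctuates on the scale of
`sqrt(2/I)/2` even with no item signal; the permutation null absorbs
this, but point estimates from few items should not be read as signal.

### Screening

Three single-pass criteria on the full cohort: (1) side bias —
P(choose right) strictly more than 2 cohort sample-SDs from the cohort
mean; (2) fast responding — trial RT under 300 ms on strictly more
than half of the responded trials; (3) value sanity — a
per-participant logistic regression of choose-right on dValue must
have a positive slope with Wald p < 0.05. Perfect separation (a
perfectly value-consistent chooser) is detected by slope blow-up and
resolved by the data direction (kept if positive). The per-participant
logistic is a vectorized Newton/IRLS fit, exact to statsmodels' Logit
at 1e-4, so screening stays negligible inside power simulations.

### Mixed-effects logistic regression

The focal models are conditional: "chose the higher-valued item"
regressed on |dValue| within the low-|dMem| half of trials (median
split, pooled across the final sample, ties to the low half in stable
order), and "chose the more memorable item" on |dMem| within the
low-|dValue| half. Exact-tie trials, whose response is undefined, are
dropped and counted.

The fitter integrates by-subject random effects (intercept +
matching slopes, unstructured covariance via a log-Cholesky
parameterization) with a Laplace approximation: a damped Newton
iteration, vectorized across subjects, finds each subject's
conditional mode, and the marginal likelihood sums the penalized
log-likelihood at the mode minus half the log-determinant of the
curvature. L-BFGS-B optimizes fixed effects and covariance jointly;
non-convergence falls back to a diagonal covariance and is flagged.
Wald CIs (reported as odds ratios per z-unit) come from the numeric
Hessian of the marginal likelihood; p-values are likelihood-ratio
tests against a refit without the focal fixed effect, random structure
retained. The approximation is validated two ways in the test suite:
against 15-node adaptive Gauss–Hermite quadrature (within 0.5 nats on
a random-intercept toy) and against lme4's `glmer` (coefficients and
log-likelihood to ~1e-4 on a shared fixture). Linear mixed models for
log RT use statsmodels MixedLM (ML), with the same LRT construction.
"Log-transformed RT" means the natural log of RT in seconds; a
logit-of-scaled-RT variant is available behind a switch.

### Bayes factors

The Bayesian refit targets the Laplace-marginal likelihood times the
priors — focal coefficient `N(0, prior_width)` (default width 1 on
standardized covariates; sensitivity grid 0.1–2), other fixed effects
`N(0, 5)`, log-Cholesky parameters `N(0, 2)` — with an adaptive
random-walk Metropolis chain whose proposal covariance comes from the
curvature at the posterior mode. BF01 is the Savage–Dickey density
ratio at zero (Gaussian KDE over the draws against the prior
ordinate), the natural estimator for a point null on one coefficient.
Acceptance rate and bulk ESS (arviz) are recorded; poor chains flag
the fit. BF magnitudes depend on prior structure and are therefore
never asserted against external values — only the direction of
evidence and the Lindley widening behaviour are tested.

### Power simulation

For each sample size the full pipeline is replayed — ratings, pairing,
side randomization, logistic choices with the focal odds ratio
injected on signed dMem, screening, median split, mixed-logistic LRT —
and detections are counted. A detection is an LRT-significant fit
whose focal coefficient has the hypothesized (positive,
memorable-items-chosen-more) sign; this directional count is what a
post-hoc power analysis of a directional hypothesis reports, and it is
the only reading under which a slightly-negative generating effect
(OR 0.97) yields single-digit power at every sample size — a
two-sided count would instead *grow* with n as the tiny negative
effect becomes detectable. A two-sided option exists and is used for
type-I calibration (generating OR 1 gives rejection at the nominal
alpha, verified at 200 replicates). The item bank and its memorability
scores are held fixed across replicates — they are measured once in
the emulated design — while participants, ratings and choices are
redrawn. Expected item CR for the power template is computed by
Gauss–Hermite quadrature over the participant-effect distribution
rather than by simulating a recognition cohort per call.

### Drift-diffusion machinery

The Wiener first-passage density uses the standard small-time /
large-time series with the usual truncation rules and automatic
switch, accurate to ~1e-6; the upper-boundary density is the lower
density under (v, w) -> (−v, 1−w). Boundaries are stimulus-coded
(upper = right item); the start point enters through an inverse-logit
link so `z_rel` stays in (0, 1); across-trial variability parameters
are fixed at zero. Simulation is Euler–Maruyama with a
Brownian-bridge within-step crossing test (plain Euler's O(sqrt(dt))
absorption bias would visibly distort RT distributions); paths not
absorbed by 10 s are recorded as no-response. Fitting is
per-participant maximum likelihood (L-BFGS-B; `t0` bounded below 95%
of the participant's minimum RT; boundary-of-space optima flagged and
dropped from group tests), with one-sample t-tests of each regression
weight across participants. A hierarchical Bayesian variant is a
deliberate non-goal: per-participant MLE plus group tests answers the
same scientific question at desk scale and deterministically.

## Problem sizes in the shipped checks

The test suite and acceptance script run every stage at sizes chosen
to keep the whole suite in the tens of minutes on one core while
leaving the statistical assertions well-powered: power curves use 100
replicates per sample size over {44, 100, 250, 500}; type-I
calibration uses 200 null replicates at the study's 44-participant
scale; split-half calibration uses 200 small cohorts; DDM group
recovery uses 6 replicates of 10 simulated participants at 138 trials
with simulation step 1e-3 s; Bayes-factor direction checks use 20
replicates of 16-participant cohorts with shortened chains. Each of
these is a scaled-down version of the corresponding full-size
procedure, not a different procedure.

## What the synthetic cohorts do not show

The generator emulates the statistical structure the analyses assume:
latent item traits, independent participants, logistic/DDM choice
rules, lognormal RTs. It does not model attention lapses, sequential
(trial-order) effects, rating drift between phases, participant
dropout, comprehension failures, or stimulus-specific semantics. A
green suite therefore certifies that the estimators are correct and
calibrated under the assumed model — it cannot certify that the
assumed model is right for any particular real dataset. The trial CSV
interchange (`memchoice.io`) exists precisely so the same inference
code can be pointed at real data.

## Known limitations

* The Laplace approximation can be biased for binary data with very
  few trials per subject; the AGQ cross-check bounds this on desk
  scales, but subjects with fewer than ~20 trials deserve caution.
* The Savage–Dickey estimate degrades when the posterior places
  essentially no mass near zero (BF01 is then a KDE tail value: the
  direction is right, the magnitude is not meaningful).
* Per-participant DDM MLE needs on the order of 100+ trials; the
  group-level t-test treats participants as exchangeable and ignores
  per-participant estimation error (a fixed-effects meta-analysis
  would weight by precision).
* The far-pair construction assumes the disjoint half-split; other
  offsets are configurable but cannot keep every item's usage at
  exactly two.
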