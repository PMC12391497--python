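# Methods

## Problem and estimands

The package quantifies how much of the association between body-mass index
and survival in older adults is mediated by epigenetic age acceleration
(EAA).  Exposure is BMI (kg/m²) from cleaned self-reported height and
weight; mediators are the age accelerations of the Horvath-I, Horvath-II,
Hannum, PhenoAge and GrimAge clocks (residuals of clock age on chronological
age) plus DunedinPACE, a pace-of-ageing measure used on its own scale
without residualisation; the outcome is all-cause mortality over roughly
four years of follow-up, modelled on the *age* timescale so every subject
enters the risk set at their own baseline age (left truncation) and is
right-censored administratively if alive at the end of follow-up.

Effects are reported on the mean-survival-time scale, in years, for an
exposed-vs-reference BMI contrast, decomposed in the potential-outcomes
framework into the average causal mediation effect (ACME: the mediator
moves from its reference-BMI to its exposed-BMI predicted value while BMI is
held fixed) and the average direct effect (ADE: BMI moves while the mediator
is held at one exposure level), each averaged over the two fixing levels.
With this symmetric averaging, ADE + ACME equals the total effect as an
algebraic identity, which the code asserts at 1e-10 on every run.
Proportion mediated, ACME/(ADE+ACME), is reported only when the two effects
share a sign.  Counterfactual outcomes average over every subject's observed
covariates and baseline age; because the same baseline age appears in both
arms of a contrast, the contrast is invariant to the residual-vs-total
survival-time distinction.

## Models

**Mediator.** Each clock's mediator is regressed by (optionally
survey-weighted) least squares on a restricted cubic spline in BMI, age, and
the covariate set shared with the outcome model (sex, ethnicity, education,
smoking, metabolic health; optionally comorbidity history or unhealthy
alcohol use).  Age enters linearly by default; a spline can be configured
per clock (default: Horvath-II, the one clock whose age relation is
nonlinear).  The residual SD (unbiased estimator) defines the predictive
distribution used by the draw-based mediation mode.

**Splines.** Restricted cubic splines use the Harrell truncated-power
construction *without* basis rescaling, so a knot vector fully determines
the basis and coefficients are bit-reproducible.  Default knot counts: 4 for
BMI and EAA, 3 for age, at the conventional quantiles (5/35/65/95% and
10/50/90%).  Knots are placed once on the full analysis sample and frozen
inside bootstrap resamples, stabilising the estimand across resamples.

**Outcome.** Gompertz proportional hazards
`h(t|x) = exp(log b + γt + xβ)` with t = age (0-based origin, so `log b` is
unconstrained).  The left-truncated, right-censored log likelihood
`Σ w_i [d_i log h(t_i) − (H(t_i) − H(a_i))]` uses an `expm1`-based stable
cumulative hazard with the exponential limit below |γ| = 1e-8.  Internally
the optimiser works with the log hazard level at age 70 instead of `log b`,
which decorrelates shape and level; fitting is Newton iteration on the
analytic gradient and Hessian (a short L-BFGS fallback handles rare stalls),
converged at gradient norm < 1e-6, with the variance from the inverse
observed information (sandwich form when survey weights are active).
Exponential and Weibull proportional-hazards comparators with identical
truncation handling support the AIC family choice.  Survey weights enter as
per-observation likelihood weights; weighted and unweighted runs can be
compared via a config flag.

**Life expectancy.** Mean residual life is the integral of the conditional
survival curve from the entry age, truncated at 130 years; the upper limit
extends automatically (doubling) while the tail bound S(T)/h(T) exceeds
1e-10, and a negative-shape fit whose survival plateaus above 1e-6 raises a
divergent-integral error rather than returning a truncated number.  Single
predictions use adaptive quadrature (absolute tolerance 1e-8); the mediation
engine uses a 64-node Gauss–Legendre rule vectorised over subjects, which
agrees with the adaptive path to well under 1e-6 years in the tested regime.

**Inference.** Uncertainty for mediation comes from a nonparametric
subject-level bootstrap (default 3000 resamples) with 95% percentile
intervals; both models are refit per resample, warm-started at the
full-sample optimum.  Non-convergent resamples are dropped and counted, with
a warning above 2%.  The quasi-Bayesian parameter-draw alternative is out of
scope.

**Mediator fixing.** The default mode substitutes the *predicted mean*
mediator value, matching the procedure the pipeline reproduces.  When the
mediator enters the outcome model nonlinearly (splined), mean substitution
is biased, so a draw-based mode (averaging outcomes over Normal(mean,
resid_sd) draws) is provided and recommended there; the two modes agree to
Monte-Carlo error for a linear mediator with modest log-hazard effect, and
a test asserts that agreement.

## Pipeline rules

Preparation: per-wave heights are cleaned within person (waves more than
one within-person SD from the within-person mean are dropped; remaining
spread above 0.05 m flags the subject), BMI = weight/height²; exclusions in
a fixed first-rule-wins order (height < 1.35 m, BMI > 60 kg/m², erratic
heights, then missingness: more than one metabolic biomarker, smoking,
weight, height, vital status) with a per-rule id log; metabolic health
classified strict (any of hypertension, hyperglycaemia,
hypertriglyceridaemia, low HDL-C present) or less-strict (at most one
component still healthy), a single missing component counting as absent;
EAA residualised on the post-exclusion sample, since residuals are
sample-relative.  The regression direction is clock-on-age (positive EAA =
epigenetically older than expected); the reverse is exposed as an option
because the convention is occasionally stated the other way.

A clock whose BMI association fails a joint Wald test of the BMI basis
(α = 0.05) cannot transmit a BMI effect and is excluded from mediation; the
pipeline applies this screen automatically.  Horvath-II is additionally
excluded from the default mediation clock list because its survival
association is weak and direction-discordant; it remains in all descriptive
outputs.  The earlier-exposure-wave preset drops the triglyceride component
from the metabolic definition (that biomarker is unavailable for the
earlier wave).  Sex-stratified runs subset the sample and drop the sex term.

## Synthetic cohort

The generator emulates the cohort the analysis was designed for: n = 3840;
baseline age truncated-Normal(69.9, 9.6) on [51, 100]; BMI
truncated-Normal(28.7, 6.1) on [15, 60]; female 58.2%; smoking
43.9/44.5/11.5% never/former/current; ethnicity 75.3/16.8/7.9%
white/black/other; ≤-high-school education 48.9%; metabolic component flags
at marginals 63.6/45.6/29.9/26.3% drawn through a Gaussian copula with a
shared loading of 0.55 and a BMI loading of 0.35, chosen so the strict and
less-strict unhealthy fractions land near 83% and 51% simultaneously (with
fixed marginals the two trade off against each other, so both cannot be
matched exactly).  Mediator links are asymmetric quadratics in BMI with
nadirs at the published per-clock values (25.4, 23.5, 25.8, 24.7 kg/m² for
Hannum/PhenoAge/GrimAge/DunedinPACE), noise SDs at the published
dispersions (5.3, 6.9, 4.8 years; 0.1 pace units), a weak linear link for
Horvath-II and no link for Horvath-I (so the Wald screen has a true
positive).  Mortality is Gompertz with shape 0.085/yr; the level −10.85 was
calibrated with the oracle so about 11% of subjects die within the
administrative window (4.5 years ± 0.5 uniform jitter) — the observed
cohort's death fraction, which, given this age structure, implies a
reference-profile life expectancy at 70 on the optimistic side of US life
tables.  Exactly one clock (default GrimAge, log-hazard 0.12 per year of
EAA, i.e. HR ≈ 1.8 per SD) carries a causal path to mortality, keeping the
single-mediator estimand well defined; the other clocks correlate with BMI
but not with the hazard, acting as built-in negative controls.  Defect rows
violating each exclusion rule can be planted in disjoint leading blocks for
preparation tests.

`true_effects_oracle` computes the ground-truth ADE/ACME/total for any
contrast by drawing covariates from the generator law and evaluating exact
conditional Gompertz survival integrals under the true structural models —
no estimation code is involved, so it serves as an independent reference
for recovery and coverage tests.

## What the synthetic data do and do not show

The generator reproduces marginals, the U-shaped links, age-timescale
mortality and administrative censoring, but not: survey design (clustering,
stratification; only per-observation weights), BMI–age dependence,
longitudinal BMI trajectories, measurement error in the clocks beyond
additive noise, or unmeasured confounding between mediator and outcome.
Passing tests therefore demonstrate that the estimators recover the effects
their models define under sequential ignorability, not that those
assumptions hold in any real cohort.

One measured limitation is deliberate: the generator's asymmetric-quadratic
BMI links are not inside the span of a restricted cubic spline, so the
spline-based procedure's asymptotic estimand differs slightly from the
structural truth (the unmodelled BMI curvature partially loads onto the
mediator coefficient).  Effect-recovery tests run under these curved
conditions at a 3-bootstrap-SE tolerance, which absorbs the gap; the
bootstrap-coverage test instead uses linear-link conditions, inside the
model span, because interval calibration is only interpretable when the
procedure's estimand and the simulation truth coincide.  On real data the
analogous statement is that spline curves approximate, not equal, the true
dose–response shapes.

## Numerical choices and problem sizes

Tolerances: likelihood-vs-quadrature agreement 1e-8; life expectancy
1e-6 years against dense trapezoid integration; decomposition identity
1e-10; EAA orthogonality 1e-8 (relative); nadir grid 0.01 kg/m² with local
quadratic refinement on [18, 45], boundary and flat profiles flagged.  The
test suite scales simulation sizes to what the properties need: parameter
recovery uses 100 cohorts of n = 5000, effect recovery 50 cohorts of
n = 4000 with bootstrap SEs pooled from three 200-resample runs, and
interval coverage 200 cohorts of n = 1000 at 300 resamples; the analysis
drivers and the acceptance script use the full n = 3840 with 300 resamples
for their intervals (the production default stays 3000).
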