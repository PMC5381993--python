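# Methods

## Model and estimand

The package estimates the cause-specific cumulative incidence of death an
occupational cohort would have experienced under hypothetical interventions
on workplace exposure, by the parametric g-formula (Monte Carlo
standardization over time-varying covariate histories). The estimand for a
cause k and age a is the probability of having died of cause k by age a in
the presence of competing causes — no hypothetical removal of competitors —
under an intervention that sets the exposure process while letting every
other part of the data-generating process (employment transitions, the other
causes of death) respond.

Identification rests on the usual g-formula assumptions: no unmeasured
confounding given the modelled covariates, positivity (interventions assign
exposure levels that occur within every covariate stratum), correct model
specification, and non-interference. The package makes these operational but
cannot verify them on real data; the natural-course calibration report is a
necessary-but-not-sufficient check of specification.

## Time and exposure conventions

* Time is discretised to whole years on the age scale; a person-period is
  the half-open interval [a, a+1) and "risk at age 70" means the cumulative
  incidence at the end of [69, 70).
* Calendar year of a period = birth year + age; birth year = entry year −
  entry age.
* Cumulative exposure is d = 0.29·L + 0.58·M + γ·11.4·H mg/m³-years over
  years in light/medium/heavy work areas, γ = 0.1 (filtration-mask
  discount).
* An increment accrued in period [a−k−1, a−k) lies at distance k years
  before age a. Hazard models use window sums over distances (2,5], (5,10]
  and (10,20] (half-open left, closed right; nothing beyond 20 years);
  the employment models use distances 0–4, i.e. exposure accrued during the
  five periods immediately preceding the current one. Only post-entry
  exposure is windowed; pre-entry exposure enters as a single linear
  baseline term.
* Cumulative work time at a row counts employed periods from entry through
  the current period inclusive.

## The six discrete-time models

Three binary pooled logistic hazards (one per cause, each fit on all at-risk
person-periods with competing deaths as non-events), two binary employment
transition models (leaving work, fit on employed rows whose next period is
observed; returning, on unemployed rows), and a proportional-odds model for
exposure category on employed rows, parameterised as
P(Y ≤ j | x) = expit(θ_j − x′β) so larger x′β means heavier exposure.
Default covariates: a restricted cubic spline in age (5 knots at the
5/27.5/50/72.5/95 percentiles of observed death ages unless fixed in the
config), linear calendar year, an age-by-year interaction, birthplace,
pre-entry work and exposure, current employment, cumulative work time and
the three exposure windows. Age and year enter centred and scaled
((x − 60)/10 and (year − 1960)/10) so all columns are O(1).

Fitting is damped Newton–Raphson with analytic gradient and Hessian,
gradient-tolerance 1e-8 (with a relative stationarity floor for very large
stacked samples), step-halving against the log-likelihood, a step-length cap
of 20 per iteration, an iteration cap of 50, warm starts at the full-sample
solution for bootstrap refits, and frequency-weight support. Standard errors
come from the inverse observed information; AIC = 2k − 2ℓ is reported per
model. Degenerate outcomes (no events, a missing ordinal category) and
separation (|coefficient| > 30 at the solution, or divergence) raise a named
error — never absorbed silently. The solvers agree with statsmodels'
`Logit` and `OrderedModel` to ~1e-5 on shared problems (tested); they exist
in-package because the nested bootstrap experiments refit all six models
thousands of times.

## Simulation algorithm

Baseline records (entry age/year, birthplace, pre-entry history) are sampled
with replacement. Each pseudo-worker advances one year at a time in a fixed
order: (1) employment transition drawn from the leave/return model using the
*previous* period's covariates (1-period lag; avoids within-period
simultaneity between exposure and leaving); (2) exposure category — ordinal
draw under the natural course when employed, forced by the intervention
otherwise (never-exposed forces a zero increment; always-X forces category X
while employed and none otherwise); (3) lagged windows rebuilt; (4) death
resolved among the competing causes; (5) age and year advance, with
administrative censoring at age 90 or the administrative end year. Under
never-exposed, employment is still simulated from the fitted models with the
intervened (zero) exposure history as input — that is precisely the
healthy-worker-survivor pathway being standardized over.

Competing causes are resolved per period by a single categorical draw with
sequentially conditioned probabilities (h_resp, h_heart(1−h_resp),
h_other(1−h_resp)(1−h_heart), remainder survives), in the fixed order
respiratory → heart → other. The fitted binary models for the later causes
therefore target h·Π(1−h_earlier) rather than h itself; at annual hazards
below ~0.02 the induced log-odds discrepancy is ≤ ~2e-3, well below
coefficient standard errors at realistic cohort sizes, and it cancels in
intervention contrasts because all arms share the same resolution rule.

Randomness: one master seed spawns a substream for baseline sampling and a
(pseudo-worker × period × draw-slot)-indexed array of uniforms for the
simulation, so results are invariant to execution order, and interventions
run from the same seed share their uniforms (common random numbers), which
removes pure Monte Carlo noise from intervention contrasts — with identical
hazards the simulated contrast is exactly zero.

## Risk estimation and contrasts

Cumulative incidence is the discrete-time Aalen–Johansen estimator with late
entry: at each age, cause-k hazard = cause-k deaths / number at risk (risk
set = entered, not yet exited; individuals entering and exiting within one
interval count in that interval's risk set); survival is the product of
one-minus-total-hazard; CIF_k(a) = Σ_{u≤a} S(u−)h_k(u). On the discrete grid
the cause-specific CIFs and survival sum to one exactly, the estimator
reduces to observed cause proportions in a closed cohort and to 1 − the
Kaplan–Meier survival with a single cause (both tested, the latter against
lifelines). Contrasts are CIF differences × 1,000 versus the no-exposure
arm; the all-cause excess is the sum of the cause-specific excesses. Years
of life lost compares total person-years between arms (truncated at the age
cap) divided by the pseudo-cohort size.

Confidence intervals are percentile bootstrap (2.5/97.5) over worker-level
resamples — person-periods within a worker are dependent — refitting all six
models per replicate (as frequency-weighted fits with the resample's
multiplicities) and rerunning every intervention. The point estimate comes
from the original sample; no bias correction. Replicate fit failures are
logged and skipped; the run aborts if more than 5% fail. The full-run
default is B = 1,500; validation experiments use B = 200.

## The synthetic cohort generator

The generator emulates a mid-century smelter workforce: ~8,000 male workers
entering follow-up in 1939–1956 after ≥1 completed year of employment
(log-normal entry ages, median ≈ 32; a third with longer pre-entry tenure),
followed to age 90 or end of 1990, with three competing causes, exposure
intensities drawn from a proportional-odds model while employed, and a
leaving-work hazard that rises by 2.3 log-odds per mg/m³-year of recent
exposure — the confounding loop that produces healthy-worker-survivor bias.
Histories are produced by running the simulation engine forward from
truth-coefficient model objects under the natural course, so generating and
fitting model forms coincide term for term and every generating coefficient
is returned in a truth record for recovery testing. Entry age and entry year
are drawn independently (their joint distribution is not separately
specified).

Default generating coefficients were calibrated once so the full-size cohort
reproduces a realistic vital-status mix (≈5% respiratory cancer, ≈20% heart
disease, ≈33% other causes dead by end of follow-up) with plausible careers
and exposure accrual, then frozen in the versioned `defaults.yaml`. What the
generator does **not** emulate: record gaps and measurement error in
exposure or cause coding, within-worker persistence of job assignments
(categories are drawn independently each employed year), unmeasured frailty
(no hidden heterogeneity beyond the modelled covariates), and smoking or
other lifestyle confounders. Passing tests therefore demonstrate that the
estimation machinery is correct under its own assumptions — not that those
assumptions hold in any real cohort.

A separate two-period toy problem (binary exposure, one binary time-varying
confounder, explicit conditional probability tables) provides an *exact*
nonparametric g-formula oracle by enumeration over its 16 survivor
histories; the parametric Monte Carlo path with saturated logistic models is
required to match it, which pins down the standardization logic end to end.

## Validation experiments and problem sizes

* Oracle equivalence: 5×10⁵ sampled individuals, saturated fits, 5×10⁵
  Monte Carlo draws; agreement within 0.005 on every intervention.
* Null-effect recovery uses a scenario whose every causal pathway from
  exposure to death is severed (direct window terms and the
  employment-channel terms in the death models are zero) while the
  exposure → leaving-work coefficient stays at 2.3, so employment paths
  still differ sharply between arms but carry no mortality signal and the
  true excess is exactly zero. Three checks: with the generating
  coefficients the simulated excess is identically zero (common random
  numbers); the fitted pipeline's mean excess over 12 independent cohorts of
  8,014 workers is within 3 standard errors of zero per cause (the
  estimator's replication noise is dominated by coefficient sampling noise,
  so a pure Monte Carlo standard error would be the wrong yardstick); and
  95% percentile bootstrap intervals (B = 200) on 40 independent cohorts of
  500 workers (middle-age entries, age cap 75, compact model specification
  sized for sparse-event refitting) cover zero at least 88% of the time for
  every cause.
* Parameter recovery: 50 cohorts of 8,000 workers; at least 90% of
  (coefficient, replicate) pairs within ±2 estimated SEs of truth, pooled
  across the ~70 coefficients of the six models (per-coefficient binomial
  checks at 50 replicates would false-alarm by chance).
* Natural-course calibration at full size: maximum observed-vs-simulated
  CIF gap through age 70 below 0.02, and the median cumulative exposure
  across person-time agreeing within 10%.
* Intervention monotonicity is asserted on the all-cause risk at ages 60 and
  70 (never ≤ light ≤ medium ≤ heavy, with a 3-SE Monte Carlo allowance).
  Cause-specific CIFs need not be monotone even when every generating
  exposure coefficient is positive: a stronger gradient on one cause removes
  susceptibles from the others' risk pools.

These sizes were chosen as the package's own validation conditions; the
experiments run in roughly a quarter of an hour on one CPU.

## Known limitations

* Annual discretisation: within-year timing of job changes and deaths is
  lost; hazards near 1 would make the discrete-time logistic approximation
  poor (not the case at realistic annual mortality).
* The never-exposed intervention extrapolates: the observed cohort contains
  almost no long unexposed careers, so the fitted models are evaluated
  outside the support of the data — a parametric assumption inherent to the
  method, visible here as wide bootstrap intervals under the null.
* Percentile bootstrap intervals can exclude the point estimate in
  pathological resamples; this is logged, not corrected.
* The proportional-odds exposure model draws categories independently across
  years; real job histories are sticky, which mainly affects the realism of
  within-worker exposure trajectories, not the estimator checks.
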