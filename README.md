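# gfcohort

Parametric g-formula estimation of cause-specific mortality under
hypothetical workplace exposure interventions, for occupational cohorts with
healthy-worker-survivor bias.

## The problem

Occupational cohort studies of airborne exposures (the motivating setting is
airborne arsenic in copper smelting) suffer a distinctive confounding
structure: healthier workers stay employed longer and therefore accrue more
exposure, while leaving work is itself predicted by recent exposure.
Employment status is then a time-varying confounder *affected by prior
exposure* — adjusting for it in a regression blocks part of the effect and
can introduce collider bias, while not adjusting leaves confounding. The
parametric g-formula handles this by **standardization**: fit models for
every component of the observed data-generating process, then simulate the
whole cohort forward under an intervention on exposure and read risks off
the simulated histories.

## The method

Person-time is discretised to one-year periods on the age scale. Six
discrete-time models are fit by maximum likelihood to the stacked
person-period records:

* pooled logistic hazard models for three competing causes of death
  (respiratory cancer, heart disease, all other causes),
* pooled logistic models for leaving work and returning to work,
* a proportional-odds (cumulative logit) model for exposure intensity
  (light / medium / heavy) while at work.

Exposure while employed is converted to a cumulative concentration metric
(mg/m³-years)

    d = 0.29·years_light + 0.58·years_medium + γ·11.4·years_heavy,   γ = 0.1,

which enters the hazards lagged two years, split into time-since-exposure
windows (2–5], (5–10] and (10–20] years, with no contribution beyond 20
years. The employment models use exposure accrued in the preceding five
years.

The Monte Carlo g-formula resamples observed baselines with replacement and
simulates each pseudo-worker year by year — employment transition (from the
previous period's covariates), exposure assignment (drawn from the ordinal
model under the *natural course*, forced by the intervention otherwise),
then death resolved among the competing causes — under five interventions:
natural course, never exposed, and always light / medium / heavy while at
work. Cause-specific cumulative incidence from age 20 is estimated from the
simulated histories with a late-entry (left-truncated) competing-risks
extension of the Kaplan–Meier estimator, and contrasts are reported as
**excess deaths per 1,000 by ages 60 and 70** relative to the no-exposure
intervention, with worker-level percentile bootstrap confidence intervals.

Because the real smelter cohort is not public, the package ships a
synthetic-cohort generator that emulates its structure — ~8,000 male
workers entering 1939–1956 after a completed year of employment, followed to
age 90 or 1990, with the exposure → leaving-work coupling (+2.3 log-odds per
mg/m³-year of recent exposure) that produces healthy-worker-survivor bias —
with every generating coefficient exposed for parameter-recovery testing,
plus a two-period toy problem with an exact enumeration oracle for the
g-formula itself.

## Worked example

```python
from gfcohort import GFormulaModel, GeneratorParams, generate_cohort

params = GeneratorParams.from_config()            # 8,014 workers
baseline, history, truth = generate_cohort(params, seed=1)

results = GFormulaModel(baseline, history).fit()  # six ML fits
print(results.summary())                          # coefficients, SEs, AIC

curves, contrasts = results.estimate(mc_size=20000, seed=1)
print(contrasts[contrasts.cause == "all_cause"].round(1).to_string(index=False))
```

which prints (deaths per 1,000; excess relative to never-exposed):

```
 age     cause  deaths_per_1000_reference  excess_per_1000_natural_course  excess_per_1000_always_light  excess_per_1000_always_medium  excess_per_1000_always_heavy
  60 all_cause                      184.4                            32.2                          25.9                           38.0                          51.4
  70 all_cause                      365.5                            59.0                          50.6                           68.4                          85.7
```

Read: by age 70, 365.5 of every 1,000 workers would have died even had
exposure been eliminated; the exposure actually experienced (natural course)
adds 59.0 deaths per 1,000, and the forced-intensity interventions show a
monotone exposure-response (50.6 → 68.4 → 85.7). On this synthetic cohort
the fitted log-odds of leaving work per mg/m³-year of recent exposure is
2.29 — the confounding loop the g-formula is standardizing over. Percentile
bootstrap intervals come from `results.bootstrap(B=...)`, and
`results.calibration_report()` compares the simulated natural course against
the observed data (maximum CIF gap through age 70 ≈ 0.006 here).

A CLI wraps the same pipeline: `gfcohort generate | fit | simulate |
estimate | run` (see `gfcohort --help`).

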