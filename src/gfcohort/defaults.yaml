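# Versioned default configuration: exposure metric constants, lag windows,
# model specifications, synthetic-cohort generating parameters, and pipeline
# defaults.  Generating coefficients are keyed by the same design-column names
# the fitting step produces, so parameter-recovery checks are well defined.

exposure:
  conc_light: 0.29
  conc_medium: 0.58
  conc_heavy: 11.4
  gamma: 0.1

lag:
  lag: 2
  windows: [[2, 5], [5, 10], [10, 20]]
  recent: [0, 4]

model_specs:
  d_resp:
    family: binary_logit
    risk_set: at_risk
    covariates: &death_covs
      [age_rcs, year, age_x_year, us_born, pre_entry_years, pre_entry_exposure,
       employed, cum_work, w_2_5, w_5_10, w_10_20]
  d_heart:
    family: binary_logit
    risk_set: at_risk
    covariates: *death_covs
  d_other:
    family: binary_logit
    risk_set: at_risk
    covariates: *death_covs
  leave_work:
    family: binary_logit
    risk_set: employed
    covariates: [age, year, cum_work, pre_entry_years, w_recent]
  return_work:
    family: binary_logit
    risk_set: unemployed
    covariates: [age, year, cum_work]
  exposure_category:
    family: proportional_odds
    risk_set: employed_now
    covariates: [age, year]

generator:
  n_workers: 8014
  entry_age_median: 31.6
  entry_age_sigma: 0.45
  entry_age_min: 20
  entry_age_max: 65
  entry_year_start: 1939
  entry_year_end: 1956
  admin_end_year: 1990
  max_age: 90
  p_us_born: 0.867
  p_exposed_at_entry: 0.974
  p_long_tenure: 0.33
  long_tenure_geometric_p: 0.12
  pre_entry_category_probs: [0.75, 0.15, 0.10]
  knots: [30.0, 45.0, 57.5, 70.0, 82.0]
  coefficients:
    d_resp:
      intercept: -6.15
      age_rcs_1: 0.70
      age_rcs_2: 0.0
      age_rcs_3: 0.0
      age_rcs_4: 0.0
      year: -0.05
      age_x_year: -0.02
      us_born: -0.10
      pre_entry_years: 0.10
      pre_entry_exposure: 0.05
      employed: -0.15
      cum_work: -0.05
      w_2_5: 0.04
      w_5_10: 0.03
      w_10_20: 0.025
    d_heart:
      intercept: -4.80
      age_rcs_1: 0.85
      age_rcs_2: 0.0
      age_rcs_3: 0.0
      age_rcs_4: 0.0
      year: -0.05
      age_x_year: -0.02
      us_born: -0.10
      pre_entry_years: 0.10
      pre_entry_exposure: 0.02
      employed: -0.15
      cum_work: -0.05
      w_2_5: 0.03
      w_5_10: 0.025
      w_10_20: 0.02
    d_other:
      intercept: -4.20
      age_rcs_1: 0.85
      age_rcs_2: 0.0
      age_rcs_3: 0.0
      age_rcs_4: 0.0
      year: -0.05
      age_x_year: -0.02
      us_born: -0.15
      pre_entry_years: 0.10
      pre_entry_exposure: 0.02
      employed: -0.25
      cum_work: -0.05
      w_2_5: 0.03
      w_5_10: 0.025
      w_10_20: 0.02
    leave_work:
      intercept: -3.60
      age: 0.35
      year: 0.05
      cum_work: -0.30
      pre_entry_years: 0.05
      w_recent: 2.30
    return_work:
      intercept: -2.90
      age: -0.50
      year: 0.0
      cum_work: 0.30
    exposure_category:
      thresh_1: 1.10
      thresh_2: 2.60
      age: -0.10
      year: -0.20

pipeline:
  interventions: [natural_course, never_exposed, always_light, always_medium, always_heavy]
  reference: never_exposed
  eval_ages: [60, 70]
  age_start: 20
  mc_size: 20000
  bootstrap_replicates: 1500
  bootstrap_replicates_test: 200
  knots: null          # null -> knots from percentiles of observed event ages
  seed: 20160819
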