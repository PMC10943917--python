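# Chronic migraine: erenumab + BSC vs placebo + BSC (>=3 prior failures,
# one of them onabotulinumtoxinA). Published point estimates; the erenumab
# price is a placeholder. The placebo responder-state MMD is fixed at half
# the baseline (the responder definition): the published 10-year arm-average
# MMD is not attainable under the baseline-reversion convention given the
# 30.26%/cycle long-term discontinuation (see docs/methods.md).
schema_version: 1
population: {population_label: CM, start_age: 41.0, fraction_female: 0.805, baseline_mmd: 18.66}
settings: {cycle_length_days: 84.0, horizon_years: 10.0, discount_rate_costs: 0.03,
  discount_rate_effects: 0.03, wtp_threshold: 30000.0, perspective: healthcare, psa_iterations: 1000,
  rng_seed: 20240315}
utility:
  intercept_u0: 0.85
  slope_per_mmd: 0.0176
  slope_se: 0.0035
  intercept_se: 0.02
  ae_disutility:
    brain_fog: {loss: 0.097, se: 0.13}
    fatigue: {loss: 0.061, se: 0.097}
    exercise_intolerance: {loss: 0.048, se: 0.092}
    insomnia: {loss: 0.048, se: 0.088}
    neck_stiffness_and_pain: {loss: 0.045, se: 0.077}
    muscle_weakness: {loss: 0.034, se: 0.058}
    sleepiness: {loss: 0.03, se: 0.059}
    constipation: {loss: 0.029, se: 0.06}
    drooping_eyelids: {loss: 0.024, se: 0.067}
    respiratory_tract_infection: {loss: 0.012, se: 0.033}
    paraesthesia: {loss: 0.012, se: 0.045}
    dizziness: {loss: 0.01, se: 0.041}
    dry_mouth: {loss: 0.01, se: 0.044}
    injection_site_pain: {loss: 0.008, se: 0.025}
    itchiness: {loss: 0.006, se: 0.023}
arms:
- name: erenumab
  role: intervention
  response_prob: 0.42
  response_prob_se: 0.0221
  response_or: null
  response_or_se: 0.0
  ae_discontinuation_prob_cycle1: 0.0106
  ae_discontinuation_se: 0.004
  longterm_discontinuation_prob_per_cycle: 0.005
  longterm_discontinuation_se: 0.0
  drug_cost_per_cycle: 500.0
  drug_cost_is_placeholder: true
  hospital_dispensed: true
  ae_incidence: {constipation: 0.08, injection_site_pain: 0.05, respiratory_tract_infection: 0.04,
    itchiness: 0.02}
  mmd_targets:
  - [522, 13.48]
  responder_mmd: null
  discontinued_mmd: null
- name: placebo
  role: comparator
  response_prob: 0.17
  response_prob_se: 0.0168
  response_or: 2.27
  response_or_se: 0.0
  ae_discontinuation_prob_cycle1: 0.0071
  ae_discontinuation_se: 0.003
  longterm_discontinuation_prob_per_cycle: 0.3026
  longterm_discontinuation_se: 0.0177
  drug_cost_per_cycle: 0.0
  drug_cost_is_placeholder: false
  hospital_dispensed: false
  ae_incidence: {respiratory_tract_infection: 0.03, dizziness: 0.02}
  mmd_targets: []
  responder_mmd: 9.33
  discontinued_mmd: null
costs:
  band_resource_use:
    no_migraine: []
    low:
    - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.05,
      hospital_dispensed_only: false}
    - {resource: emergency_visit, unit_cost: 227.7, units: 1.0, fraction: 0.29, hospital_dispensed_only: false}
    - {resource: primary_care_visit, unit_cost: 74.87, units: 1.0, fraction: 0.97,
      hospital_dispensed_only: false}
    - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 0.04,
      hospital_dispensed_only: false}
    intermediate:
    - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.07,
      hospital_dispensed_only: false}
    - {resource: emergency_visit, unit_cost: 227.7, units: 1.0, fraction: 0.54, hospital_dispensed_only: false}
    - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 0.5,
      hospital_dispensed_only: false}
    - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
    high:
    - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.07,
      hospital_dispensed_only: false}
    - {resource: emergency_visit, unit_cost: 227.7, units: 1.0, fraction: 0.74, hospital_dispensed_only: false}
    - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 1.0,
      hospital_dispensed_only: false}
    - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
    chronic:
    - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.17,
      hospital_dispensed_only: false}
    - {resource: emergency_visit, unit_cost: 227.7, units: 1.0, fraction: 0.72, hospital_dispensed_only: false}
    - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 1.0,
      hospital_dispensed_only: false}
    - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
  acute_med_cost_range:
    no_migraine: {triptans_low: 0.0, triptans_high: 0.0, other_low: 3.56, other_high: 3.56}
    low: {triptans_low: 0.8, triptans_high: 3.8, other_low: 6.2, other_high: 8.2}
    intermediate: {triptans_low: 5.3, triptans_high: 9.7, other_low: 6.2, other_high: 8.2}
    high: {triptans_low: 11.2, triptans_high: 20.2, other_low: 8.9, other_high: 12.9}
    chronic: {triptans_low: 21.7, triptans_high: 41.1, other_low: 13.5, other_high: 22.2}
  statutory_discount_pct: 7.5
  wage_monthly: 2847.1
  working_days_per_month: 22.0
  unemployment_rate: 0.127
  presenteeism_day_fraction: 0.5
  inflation_multiplier: 1.0
  resource_cost_se_frac: 0.2
work_loss:
  absenteeism: {intercept: 0.3, slope_per_mmd: 0.45, intercept_se: 0.1, slope_se: 0.05}
  presenteeism: {intercept: 0.5, slope_per_mmd: 0.95, intercept_se: 0.15, slope_se: 0.08}
  wpai_presenteeism: {intercept: 0.5, slope_per_mmd: 1.1, intercept_se: 0.15, slope_se: 0.09}
life_table_csv: lifetable_synthetic.csv
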