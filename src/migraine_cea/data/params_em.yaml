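# Episodic migraine: erenumab + BSC vs topiramate + BSC.
# Published point estimates; drug prices are placeholders (not public).
schema_version: 1
population:
  population_label: EM
  start_age: 41.0
  fraction_female: 0.805
  baseline_mmd: 9.44
settings:
  cycle_length_days: 84.0
  horizon_years: 10.0
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  wtp_threshold: 30000.0
  perspective: healthcare
  psa_iterations: 1000
  rng_seed: 20240315
utility:
  intercept_u0: 0.85
  slope_per_mmd: 0.0176
  slope_se: 0.0035
  intercept_se: 0.02          # not published; package default for sampling
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
    response_prob: 0.37
    response_prob_se: 0.0216      # binomial scale at trial-size n; not published
    response_or: null
    response_or_se: 0.0
    ae_discontinuation_prob_cycle1: 0.0552
    ae_discontinuation_se: 0.011
    longterm_discontinuation_prob_per_cycle: 0.005
    longterm_discontinuation_se: 0.0
    drug_cost_per_cycle: 500.0
    drug_cost_is_placeholder: true
    hospital_dispensed: true
    ae_incidence:                 # per assessment period; package defaults
      constipation: 0.08
      injection_site_pain: 0.05
      respiratory_tract_infection: 0.04
      itchiness: 0.02
    mmd_targets: [[12, 6.95], [24, 7.23], [108, 7.42]]
    responder_mmd: null
    discontinued_mmd: null
  - name: topiramate
    role: comparator
    response_prob: 0.18
    response_prob_se: 0.0172
    response_or: 2.76
    response_or_se: 1.16
    ae_discontinuation_prob_cycle1: 0.3557
    ae_discontinuation_se: 0.024
    longterm_discontinuation_prob_per_cycle: 0.051
    longterm_discontinuation_se: 0.0112
    drug_cost_per_cycle: 30.0
    drug_cost_is_placeholder: true
    hospital_dispensed: false
    ae_incidence:
      paraesthesia: 0.3
      fatigue: 0.12
      brain_fog: 0.1
      dizziness: 0.08
      sleepiness: 0.07
    mmd_targets: [[12, 8.56], [24, 8.65], [108, 8.86]]
    responder_mmd: null
    discontinued_mmd: null
costs:
  band_resource_use:
    no_migraine: []
    low:
      - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.05, hospital_dispensed_only: false}
      - {resource: emergency_visit, unit_cost: 227.70, units: 1.0, fraction: 0.29, hospital_dispensed_only: false}
      - {resource: primary_care_visit, unit_cost: 74.87, units: 1.0, fraction: 0.97, hospital_dispensed_only: false}
      - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 0.04, hospital_dispensed_only: false}
    intermediate:
      - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.07, hospital_dispensed_only: false}
      - {resource: emergency_visit, unit_cost: 227.70, units: 1.0, fraction: 0.54, hospital_dispensed_only: false}
      - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 0.50, hospital_dispensed_only: false}
      - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
    high:
      - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.07, hospital_dispensed_only: false}
      - {resource: emergency_visit, unit_cost: 227.70, units: 1.0, fraction: 0.74, hospital_dispensed_only: false}
      - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 1.0, hospital_dispensed_only: false}
      - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
    chronic:
      - {resource: hospitalisation, unit_cost: 2044.61, units: 1.0, fraction: 0.17, hospital_dispensed_only: false}
      - {resource: emergency_visit, unit_cost: 227.70, units: 1.0, fraction: 0.72, hospital_dispensed_only: false}
      - {resource: neurologist_visit, unit_cost: 104.36, units: 1.0, fraction: 1.0, hospital_dispensed_only: false}
      - {resource: pharmacy_visit, unit_cost: 5.89, units: 1.0, fraction: 1.0, hospital_dispensed_only: true}
  acute_med_cost_range:
    no_migraine: {triptans_low: 0.0, triptans_high: 0.0, other_low: 3.56, other_high: 3.56}
    low: {triptans_low: 0.80, triptans_high: 3.80, other_low: 6.20, other_high: 8.20}
    intermediate: {triptans_low: 5.30, triptans_high: 9.70, other_low: 6.20, other_high: 8.20}
    high: {triptans_low: 11.20, triptans_high: 20.20, other_low: 8.90, other_high: 12.90}
    chronic: {triptans_low: 21.70, triptans_high: 41.10, other_low: 13.50, other_high: 22.20}
  statutory_discount_pct: 7.5
  wage_monthly: 2847.10
  working_days_per_month: 22.0
  unemployment_rate: 0.127
  presenteeism_day_fraction: 0.5
  inflation_multiplier: 1.0
  resource_cost_se_frac: 0.2
work_loss:
  # regression coefficients (days per 3-month window vs MMD); the source
  # trial-level fits are not published — package defaults on the order of
  # magnitude implied by the reported societal cost totals
  absenteeism: {intercept: 0.3, slope_per_mmd: 0.45, intercept_se: 0.1, slope_se: 0.05}
  presenteeism: {intercept: 0.5, slope_per_mmd: 0.95, intercept_se: 0.15, slope_se: 0.08}
  wpai_presenteeism: {intercept: 0.5, slope_per_mmd: 1.1, intercept_se: 0.15, slope_se: 0.09}
life_table_csv: lifetable_synthetic.csv
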