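adverse:
  annual_prob_background: 0.0
  annual_prob_treated: 0.02
  cost_per_event: 400.0
  disutility: 0.05
comparator_treatment_delay: never
costs:
  annual_drug_cost: 30.0
  annual_monitoring_cost: 45.0
  event_year_cost:
    heart_failure: 5900.0
    mi: 4800.0
    stable_angina: 2300.0
    stroke: 11500.0
    tia: 1600.0
    unstable_angina: 3900.0
  fatal_event_cost: 1700.0
  post_event_annual_cost:
    heart_failure: 1300.0
    mi: 280.0
    stable_angina: 250.0
    stroke: 2100.0
    tia: 120.0
    unstable_angina: 280.0
effect:
  n_drugs_scenario: 1 drug
  rr:
    fatal_cvd: 0.85
    heart_failure: 0.72
    mi: 0.85
    stable_angina: 0.9
    stroke: 0.75
    tia: 0.8
    unstable_angina: 0.88
excess_death_to_cvd: true
max_annual_risk: 0.95
mortality:
  smr:
    heart_failure: 3.0
    mi: 2.5
    stable_angina: 1.4
    stroke: 2.2
    tia: 1.5
    unstable_angina: 1.8
profile:
  r10: 0.1
  sex: male
  start_age: 60
risk_increment: 0.001
schema_version: 1
settings:
  currency_year: 2016/17
  cycle_length: 1.0
  discount_rate_costs: 0.035
  discount_rate_qalys: 0.035
  max_age: 100
  max_cycles: 60
  wtp_threshold: 20000.0
tables:
  age_factors: rr_age_factors.csv
  baseline_utility: baseline_utility.csv
  events: events.csv
  lifetable: lifetable.csv
utilities:
  event_multiplier:
    heart_failure: 0.68
    mi: 0.76
    stable_angina: 0.81
    stroke: 0.63
    tia: 0.9
    unstable_angina: 0.77
  post_multiplier:
    heart_failure: 0.75
    mi: 0.88
    stable_angina: 0.88
    stroke: 0.65
    tia: 0.96
    unstable_angina: 0.88
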