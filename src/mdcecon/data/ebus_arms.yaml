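traditional:
  arm: traditional
  n_procedures: 3
  n_eligible: 20
  prop_under65: 0.3333333333333333
  procedure_cost: 1577.0
  parking_cost_per_visit: 9.0
  prop_requiring_parking: 0.5
  travel_cost_per_visit: 59.14
  hours_forgone: 7.5
  caregivers_per_procedure: 1.0
  caregiver_employment_prop: 0.5
  wage_per_hour: 29.55
  qaly_per_procedure: 0.071
mdc:
  arm: mdc
  n_procedures: 57
  n_eligible: 95
  prop_under65: 0.3333333333333333
  procedure_cost: 1577.0
  parking_cost_per_visit: 9.0
  prop_requiring_parking: 0.5
  travel_cost_per_visit: 59.14
  hours_forgone: 7.5
  caregivers_per_procedure: 1.0
  caregiver_employment_prop: 0.5
  wage_per_hour: 29.55
  qaly_per_procedure: 0.071
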