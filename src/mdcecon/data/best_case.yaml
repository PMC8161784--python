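- name: best_case
  overrides:
    parking_cost_per_visit: 4.5
    clinic_visit_hours: 0.925
    caregiver_employment_prop: 0.25
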