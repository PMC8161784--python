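- name: worst_case
  overrides:
    parking_cost_per_visit: 12.0
    hours_off_work_override: 7.5
    override_applies_to: both
    caregiver_employment_prop: 0.75
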