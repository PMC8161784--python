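visits_saved_per_patient: 1.06
n_patients: 350
caregivers_per_visit: 1.25
prop_under65: 0.23
parking_cost_per_visit: 6.0
travel_cost_per_visit: 59.14
return_distance_km: null
travel_rate_per_km: null
clinic_visit_hours: 1.26
time_forgone_hours: 1.27
wage_per_hour: 29.55
caregiver_employment_prop: 0.5
admin_cost_per_visit: 1.37
hours_off_work_override: null
override_applies_to: both
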