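visit_max: 8
traditional:
  name: traditional
  n: 78
  stage_props:
    '1': 0.3076923076923077
    '2': 0.07692307692307693
    '3': 0.1794871794871795
    '4': 0.3717948717948718
    undetermined: 0.0641025641025641
  diagnosis_props:
    NSCLC: 0.8846153846153846
    SCLC: 0.11538461538461539
    presumed_LC: 0.0
    non_LC: 0.0
  stage_visit_means:
    '1': 2.29
    '2': 2.33
    '3': 3.43
    '4': 2.55
  overall_visit_mean: 2.68
  biopsies_mean: 1.32
  imaging_mean: 2.24
  ebus_prop: 0.15
  treatment_props:
    1:TS: 0.20833333333333334
    1:RT: 0.875
    2:TS: 0.3333333333333333
    2:RT: 0.8333333333333334
    3:ST+RT: 0.5714285714285714
    4:ST: 0.3793103448275862
  age_mean: 70.0
  age_sd: 9.7
  under65_frac: 0.23
  distance_mean_km: 102.0
  distance_sigma: 0.5
  caregiver_probs:
  - 0.8
  - 0.16
  - 0.03
  - 0.01
mdc:
  name: mdc
  n: 350
  stage_props:
    '1': 0.31142857142857144
    '2': 0.07428571428571429
    '3': 0.19714285714285715
    '4': 0.4085714285714286
    undetermined: 0.008571428571428572
  diagnosis_props:
    NSCLC: 0.7428571428571429
    SCLC: 0.12857142857142856
    presumed_LC: 0.12857142857142856
    non_LC: 0.0
  stage_visit_means:
    '1': 1.66
    '2': 2.13
    '3': 2.03
    '4': 1.29
  overall_visit_mean: 1.62
  biopsies_mean: 1.17
  imaging_mean: 2.02
  ebus_prop: 0.6
  treatment_props:
    1:TS: 0.13761467889908258
    1:RT: 0.7706422018348624
    2:TS: 0.23076923076923078
    2:RT: 0.6538461538461539
    3:ST+RT: 0.5362318840579711
    4:ST: 0.3986013986013986
  age_mean: 71.7
  age_sd: 9.1
  under65_frac: 0.2257142857142857
  distance_mean_km: 102.0
  distance_sigma: 0.5
  caregiver_probs:
  - 0.8
  - 0.16
  - 0.03
  - 0.01
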