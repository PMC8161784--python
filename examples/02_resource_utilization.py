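"""Compare health-resource utilization between the two clinic models.

Builds the full between-arm comparison table on a calibrated synthetic
cohort: mean oncology visits from diagnosis to first treatment (overall and
per stage), mean biopsies and staging imaging per patient, EBUS-TBNA uptake
among stage-2/3 patients, and treatment-received proportions. Means carry
Welch t-tests; proportions carry chi-squared tests (Fisher's exact when
expected cell counts fall below 5).
"""

from mdcecon import default_spec, generate_cohort, utilization_report
from mdcecon.utilization import report_to_frame

cohort = generate_cohort(default_spec(), seed=42)
frame = report_to_frame(utilization_report(cohort))

frame["display"] = frame["traditional"].round(2).astype(str) + " vs " + \
    frame["mdc"].round(2).astype(str)

print(frame[["section", "label", "display", "test", "p_value"]]
      .to_string(index=False))

# Consolidating consultations roughly halves oncology visits before first
# treatment (2.68 vs 1.62 overall, p << 0.001) and sharply raises
# guideline-recommended invasive mediastinal staging (15% vs 60%), while
# biopsies, imaging and treatments received stay comparable. Note the
# per-stage p-values are computed on the synthetic visit distributions, so
# only the means — not the dispersion — mirror the source cohort.
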