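"""Cost-effectiveness of increased invasive mediastinal staging.

Consolidated care raised EBUS-TBNA staging uptake among stage-2/3 patients
from 3/20 to 57/95 procedures, adding procedure, out-of-pocket and
productivity costs. This example assembles both arms' pathway costs,
attaches 0.071 QALYs per procedure, and compares the incremental cost per
QALY with a CAD 80,000/QALY willingness-to-pay threshold.
"""

from mdcecon import (cost_effectiveness_verdict, incremental_analysis,
                     mdc_arm_defaults, traditional_arm_defaults)
from mdcecon.icer import result_to_rows

result = incremental_analysis(traditional_arm_defaults(), mdc_arm_defaults(),
                              wtp=80_000)

print(f"{'':<32s}{'traditional':>12s}{'mdc':>12s}")
for label, trad, mdc in result_to_rows(result):
    t = "" if trad is None else f"{trad:,}"
    m = "" if mdc is None else f"{mdc:,}"
    print(f"{label:<32s}{t:>12s}{m:>12s}")

print()
print(cost_effectiveness_verdict(result)["narrative"])

# The added staging costs ~CAD 98.6k but yields 3.83 incremental QALYs:
# about CAD 25,709 per QALY, well under the CAD 80,000 threshold (which
# would require only a 1.23-QALY gain), so the uptake increase is
# cost-effective despite the higher spending.
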