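"""Consolidated report assembly over the pipeline stages.

Every number in the report is produced by a module operation (cohort
summary, utilization comparisons, cost breakdown, scenario range, ICER);
this layer only arranges results and serializes them. Reports are pure
functions of (inputs, seed), so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from . import costmodel, icer, sensitivity, utilization
from .cohort import CohortSpec, default_spec, generate_cohort, summarize_cohort


def full_analysis(cohort=None, *, spec: CohortSpec | None = None, seed: int = 0,
                  params: costmodel.CostParameters | None = None,
                  scenarios=None,
                  ebus_arms: dict | None = None,
                  wtp: float = icer.WTP_DEFAULT,
                  extrapolate_to: float | None = 585) -> dict:
    """Run every stage and assemble one machine-readable report.

    A cohort may be passed in; otherwise one is generated (calibrated) from
    ``spec`` (packaged default if omitted) with ``seed``. Cost parameters,
    scenarios and EBUS arm parameters default to the packaged base case,
    the best/worst pair, and the published arm inputs respectively.
    """
    if cohort is None:
        cohort = generate_cohort(spec or default_spec(), seed=seed, calibrated=True)
    params = params or costmodel.CostParameters()
    scenarios = list(scenarios) if scenarios is not None else [
        sensitivity.BEST_CASE, sensitivity.WORST_CASE]
    ebus_arms = ebus_arms or {"traditional": icer.traditional_arm_defaults(),
                              "mdc": icer.mdc_arm_defaults()}

    summary = summarize_cohort(cohort)
    util_rows = utilization.utilization_report(cohort)
    breakdown = costmodel.total_savings(params)
    lo, hi, table = sensitivity.multiway_range(params, scenarios)
    ebus = icer.incremental_analysis(ebus_arms["traditional"], ebus_arms["mdc"],
                                     wtp=wtp)

    util_records = [
        {k: (None if isinstance(v, float) and math.isnan(v) else v)
         for k, v in rec.items()}
        for rec in utilization.report_to_frame(util_rows).to_dict(orient="records")]

    report = {
        "seed": seed,
        "cohort_summary": summary,
        "utilization": util_records,
        "cost": {
            "reported": breakdown.reported,
            "unrounded_grand_total": breakdown.grand_total,
            "per_patient_unrounded": breakdown.per_patient,
        },
        "sensitivity": {
            "range": [lo, hi],
            "scenarios": {name: b.reported for name, b in table},
        },
        "icer": {**icer.result_to_dict(ebus),
                 "verdict": icer.cost_effectiveness_verdict(ebus)},
    }
    if extrapolate_to is not None:
        report["cost"]["extrapolated"] = {
            "target_n_patients": extrapolate_to,
            "total_savings": costmodel.extrapolate(breakdown, extrapolate_to),
        }
    return report


def write_report(report: dict, outdir, formats=("json",), stem="report") -> list:
    """Serialize the report; returns the paths written.

    JSON gets the full nested report; CSV gets the flat utilization table
    plus two-column cost and threshold tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = outdir / f"{stem}.json"
        path.write_text(json.dumps(report, indent=2, default=str) + "\n")
        written.append(path)
    if "csv" in formats:
        import pandas as pd

        util = pd.DataFrame(report["utilization"])
        p1 = outdir / f"{stem}_utilization.csv"
        util.to_csv(p1, index=False)
        written.append(p1)

        cost_rows = [{"item": k, "value": v} for k, v in report["cost"]["reported"].items()]
        p2 = outdir / f"{stem}_cost.csv"
        pd.DataFrame(cost_rows).to_csv(p2, index=False)
        written.append(p2)

        ic = report["icer"]
        icer_rows = [{"item": k, "value": v} for k, v in ic.items() if k != "verdict"]
        p3 = outdir / f"{stem}_icer.csv"
        pd.DataFrame(icer_rows).to_csv(p3, index=False)
        written.append(p3)
    return written
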