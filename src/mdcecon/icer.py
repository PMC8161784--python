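"""Cost-effectiveness of invasive mediastinal staging by EBUS-TBNA.

Uptake of guideline-recommended invasive mediastinal staging
(endobronchial ultrasound transbronchial needle aspiration) among stage-2/3
patients rose sharply under the consolidated clinic, raising procedure
costs. This module assembles the per-arm pathway cost (procedure,
out-of-pocket, productivity loss), attaches a per-procedure QALY gain, and
computes the incremental cost-effectiveness ratio (ICER)

    ICER = (cost_mdc - cost_traditional) / (qaly_mdc - qaly_traditional)

against a willingness-to-pay (WTP) threshold, plus the threshold quantity:
the QALY difference needed for the incremental cost to be acceptable at
the WTP (incremental cost / WTP).

Conventions: all arm totals and the ICER use unrounded intermediates; the
*displayed* QALY difference follows the table presentation (per-arm QALYs
rounded to 2 decimals, then subtracted). The per-procedure QALY default is
0.071, drawn from a same-jurisdiction conscious-sedation costing; an
alternative published value of 0.015 can be configured but is not the
default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from ._util import round_half_away

WTP_DEFAULT = 80_000.0


class IcerError(ValueError):
    """Invalid EBUS arm parameters."""


@dataclass(frozen=True)
class EbusArmParameters:
    """Per-arm inputs to the EBUS-TBNA pathway cost.

    ``n_procedures`` of ``n_eligible`` stage-2/3 patients underwent the
    procedure (3/20 traditional, 57/95 MDC). ``prop_under65`` is the
    working-age fraction *of procedures* (1/3 and 19/57); parking is
    incurred by ``prop_requiring_parking`` of procedures; each procedure
    needs ``caregivers_per_procedure`` caregivers (for transport home), of
    whom ``caregiver_employment_prop`` forgo paid work for
    ``hours_forgone`` hours.
    """

    arm: str
    n_procedures: int
    n_eligible: int
    prop_under65: float
    procedure_cost: float = 1577.0
    parking_cost_per_visit: float = 9.00
    prop_requiring_parking: float = 0.50
    travel_cost_per_visit: float = 59.14
    hours_forgone: float = 7.5
    caregivers_per_procedure: float = 1.0
    caregiver_employment_prop: float = 0.50
    wage_per_hour: float = 29.55
    qaly_per_procedure: float = 0.071

    def __post_init__(self):
        if self.n_procedures < 0 or self.n_eligible < 0:
            raise IcerError("counts must be non-negative")
        if self.n_procedures > self.n_eligible:
            raise IcerError("n_procedures cannot exceed n_eligible")
        for f in ("prop_under65", "prop_requiring_parking", "caregiver_employment_prop"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise IcerError(f"{f} must lie in [0, 1]")
        for f in ("procedure_cost", "parking_cost_per_visit", "travel_cost_per_visit",
                  "hours_forgone", "caregivers_per_procedure", "wage_per_hour",
                  "qaly_per_procedure"):
            if getattr(self, f) < 0:
                raise IcerError(f"{f} must be non-negative")


def traditional_arm_defaults() -> EbusArmParameters:
    """Traditional arm: 3 procedures among 20 eligible, 1/3 under 65."""
    return EbusArmParameters(arm="traditional", n_procedures=3, n_eligible=20,
                             prop_under65=1 / 3)


def mdc_arm_defaults() -> EbusArmParameters:
    """MDC arm: 57 procedures among 95 eligible, 19/57 under 65."""
    return EbusArmParameters(arm="mdc", n_procedures=57, n_eligible=95,
                             prop_under65=19 / 57)


@dataclass(frozen=True)
class ArmCosts:
    """Unrounded per-arm cost components (CAD) and QALYs."""

    arm: str
    procedural_cost: float
    parking_cost: float
    travel_cost: float
    patient_productivity: float
    caregiver_productivity: float
    qalys: float

    @property
    def out_of_pocket_total(self) -> float:
        return self.parking_cost + self.travel_cost

    @property
    def productivity_total(self) -> float:
        return self.patient_productivity + self.caregiver_productivity

    @property
    def total_cost(self) -> float:
        return self.procedural_cost + self.out_of_pocket_total + self.productivity_total

    @property
    def reported(self) -> dict:
        return {
            "procedural_cost": round_half_away(self.procedural_cost),
            "parking_cost": round_half_away(self.parking_cost),
            "travel_cost": round_half_away(self.travel_cost),
            "out_of_pocket_total": round_half_away(self.out_of_pocket_total),
            "patient_productivity": round_half_away(self.patient_productivity),
            "caregiver_productivity": round_half_away(self.caregiver_productivity),
            "productivity_total": round_half_away(self.productivity_total),
            "total_cost": round_half_away(self.total_cost),
            "qalys": round(self.qalys, 2),
        }


def arm_costs(p: EbusArmParameters) -> ArmCosts:
    """Assemble one arm's pathway costs and QALYs, unrounded."""
    n = p.n_procedures
    return ArmCosts(
        arm=p.arm,
        procedural_cost=n * p.procedure_cost,
        parking_cost=n * p.parking_cost_per_visit * p.prop_requiring_parking,
        travel_cost=n * p.travel_cost_per_visit,
        patient_productivity=n * p.prop_under65 * p.hours_forgone * p.wage_per_hour,
        caregiver_productivity=(n * p.caregivers_per_procedure
                                * p.caregiver_employment_prop
                                * p.hours_forgone * p.wage_per_hour),
        qalys=arm_qalys(p),
    )


def arm_qalys(p: EbusArmParameters) -> float:
    """Total QALYs attributed to the arm's procedures (unrounded)."""
    return p.n_procedures * p.qaly_per_procedure


@dataclass(frozen=True)
class EbusResult:
    """Incremental cost-effectiveness of the MDC staging pathway."""

    traditional: ArmCosts
    mdc: ArmCosts
    wtp_threshold: float
    incremental_cost: float
    incremental_qalys: float
    cost_per_qaly: float | None          # None when incremental QALYs are 0
    displayed_qaly_difference: float     # rounded-arm presentation
    qalys_needed_at_wtp: float

    @property
    def icer_defined(self) -> bool:
        return self.cost_per_qaly is not None

    @property
    def cost_effective(self) -> bool:
        return (self.incremental_qalys > 0 and self.icer_defined
                and self.cost_per_qaly <= self.wtp_threshold)


def incremental_analysis(traditional: EbusArmParameters, mdc: EbusArmParameters,
                         wtp: float = WTP_DEFAULT) -> EbusResult:
    """ICER and WTP-threshold quantities from unrounded arm totals.

    When the QALY difference is zero the ICER is flagged undefined
    (``cost_per_qaly=None``) rather than reported as a number.
    """
    if wtp <= 0:
        raise IcerError("willingness-to-pay threshold must be positive")
    a, b = arm_costs(traditional), arm_costs(mdc)
    inc_cost = b.total_cost - a.total_cost
    inc_q = b.qalys - a.qalys
    return EbusResult(
        traditional=a,
        mdc=b,
        wtp_threshold=wtp,
        incremental_cost=inc_cost,
        incremental_qalys=inc_q,
        cost_per_qaly=(inc_cost / inc_q) if inc_q != 0 else None,
        displayed_qaly_difference=round(b.qalys, 2) - round(a.qalys, 2),
        qalys_needed_at_wtp=inc_cost / wtp,
    )


def cost_effectiveness_verdict(result: EbusResult) -> dict:
    """Boolean verdict plus narrative fields (observed vs needed QALYs)."""
    if not result.icer_defined:
        narrative = ("ICER undefined: the arms gain identical QALYs, so no "
                     "cost-per-QALY can be attributed to the added spending.")
    else:
        relation = "falls below" if result.cost_effective else "exceeds"
        narrative = (
            f"Incremental cost CAD {result.incremental_cost:,.0f} for "
            f"{result.incremental_qalys:.3f} QALYs "
            f"(CAD {result.cost_per_qaly:,.0f}/QALY), which {relation} the "
            f"willingness-to-pay threshold of CAD {result.wtp_threshold:,.0f}/QALY. "
            f"At that threshold a gain of at least "
            f"{result.qalys_needed_at_wtp:.2f} QALYs is required; the observed "
            f"difference is {result.displayed_qaly_difference:.2f} QALYs.")
    return {
        "cost_effective": result.cost_effective,
        "icer_defined": result.icer_defined,
        "observed_qaly_difference": result.displayed_qaly_difference,
        "qalys_needed_at_wtp": round(result.qalys_needed_at_wtp, 2),
        "narrative": narrative,
    }


# ---------------------------------------------------------------------------
# serialization

def arm_params_from_dict(d: dict) -> EbusArmParameters:
    try:
        return EbusArmParameters(**d)
    except TypeError as exc:
        raise IcerError(f"bad EBUS arm parameter field: {exc}") from exc


def load_arm_parameters(path) -> dict:
    """Read {'traditional': EbusArmParameters, 'mdc': ...} from YAML/JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out = {}
    for arm in ("traditional", "mdc"):
        if arm not in data:
            raise IcerError(f"EBUS parameter file missing arm {arm!r}")
        ad = dict(data[arm])
        ad.setdefault("arm", arm)
        out[arm] = arm_params_from_dict(ad)
    return out


def result_to_dict(result: EbusResult) -> dict:
    return {
        "traditional": result.traditional.reported,
        "mdc": result.mdc.reported,
        "incremental_cost": result.incremental_cost,
        "incremental_qalys": result.incremental_qalys,
        "displayed_qaly_difference": result.displayed_qaly_difference,
        "cost_per_qaly": result.cost_per_qaly,
        "wtp_threshold": result.wtp_threshold,
        "qalys_needed_at_wtp": result.qalys_needed_at_wtp,
        "cost_effective": result.cost_effective,
    }


def result_to_rows(result: EbusResult) -> list:
    """Threshold-analysis table rows: (label, traditional, mdc)."""
    a, b = result.traditional.reported, result.mdc.reported
    rows = [
        ("Quality-adjusted life years", a["qalys"], b["qalys"]),
        ("EBUS-TBNA procedural cost", a["procedural_cost"], b["procedural_cost"]),
        ("Parking cost", a["parking_cost"], b["parking_cost"]),
        ("Return travel cost", a["travel_cost"], b["travel_cost"]),
        ("Total out-of-pocket costs", a["out_of_pocket_total"], b["out_of_pocket_total"]),
        ("Patient opportunity cost", a["patient_productivity"], b["patient_productivity"]),
        ("Caregiver opportunity cost", a["caregiver_productivity"], b["caregiver_productivity"]),
        ("Total productivity loss costs", a["productivity_total"], b["productivity_total"]),
        ("Total EBUS-TBNA cost", a["total_cost"], b["total_cost"]),
        ("Cost per QALY",
         None if result.cost_per_qaly is None else round_half_away(result.cost_per_qaly),
         None),
    ]
    return rows
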