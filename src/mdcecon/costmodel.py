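"""Societal-perspective cost-savings model for the consolidated clinic.

The base-case model monetizes the visits a consolidated multidisciplinary
clinic saves relative to sequential referral, in three categories:

* out-of-pocket savings — parking and return travel per avoided visit;
* productivity-loss savings — the human-capital approach: hours away from
  work (clinic visit duration plus time forgone travelling, parking and
  finding the clinic) times the average hourly wage, counted for working-age
  (<65) patients and for the employed fraction of accompanying caregivers;
* administrative savings — clerk time no longer spent booking each visit.

All intermediates are kept unrounded; reported (display) figures follow a
fixed convention (see ``CostBreakdown.reported``): line items round to the
nearest dollar half away from zero, the out-of-pocket category rounds from
its exact sum, the productivity category sums its rounded line items, and
the grand total is the sum of the three reported category totals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from ._util import round_half_away


class CostModelError(ValueError):
    """Invalid cost-model parameters."""


_FRACTION_FIELDS = ("prop_under65", "caregiver_employment_prop")
_NONNEG_FIELDS = (
    "visits_saved_per_patient", "caregivers_per_visit", "parking_cost_per_visit",
    "clinic_visit_hours", "time_forgone_hours", "wage_per_hour",
    "admin_cost_per_visit",
)
APPLY_CHOICES = ("patients", "caregivers", "both")


@dataclass(frozen=True)
class CostParameters:
    """Unit variables of the base-case visit-savings model.

    Defaults are the base case: 1.06 visits saved per patient over 350
    patients, 1.25 caregivers per visit, 23% of patients under 65, CAD 6.00
    parking and CAD 59.14 return travel per visit, 1.26 h clinic visit plus
    1.27 h forgone, CAD 29.55/h wage, 50% of caregivers employed, and
    CAD 1.37 administrative cost per booked visit.

    Travel can instead be specified as a distance mode — set
    ``travel_cost_per_visit=None`` and give ``return_distance_km`` and
    ``travel_rate_per_km`` (e.g. 102.0 km at CAD 0.58/km); exactly one mode
    must be active. ``hours_off_work_override`` replaces clinic + forgone
    hours for the parties named by ``override_applies_to``.
    """

    visits_saved_per_patient: float = 1.06
    n_patients: int = 350
    caregivers_per_visit: float = 1.25
    prop_under65: float = 0.23
    parking_cost_per_visit: float = 6.00
    travel_cost_per_visit: float | None = 59.14
    return_distance_km: float | None = None
    travel_rate_per_km: float | None = None
    clinic_visit_hours: float = 1.26
    time_forgone_hours: float = 1.27
    wage_per_hour: float = 29.55
    caregiver_employment_prop: float = 0.50
    admin_cost_per_visit: float = 1.37
    hours_off_work_override: float | None = None
    override_applies_to: str = "both"

    def __post_init__(self):
        if self.n_patients <= 0:
            raise CostModelError("n_patients must be positive")
        for f in _NONNEG_FIELDS:
            if getattr(self, f) < 0:
                raise CostModelError(f"{f} must be non-negative")
        for f in _FRACTION_FIELDS:
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise CostModelError(f"{f} must lie in [0, 1]")
        distance_mode = self.return_distance_km is not None or self.travel_rate_per_km is not None
        if distance_mode:
            if self.travel_cost_per_visit is not None:
                raise CostModelError(
                    "travel_cost_per_visit and distance mode are mutually exclusive")
            if self.return_distance_km is None or self.travel_rate_per_km is None:
                raise CostModelError(
                    "distance mode needs both return_distance_km and travel_rate_per_km")
            if self.return_distance_km < 0 or self.travel_rate_per_km < 0:
                raise CostModelError("distance-mode fields must be non-negative")
        elif self.travel_cost_per_visit is None:
            raise CostModelError("one travel specification mode must be active")
        elif self.travel_cost_per_visit < 0:
            raise CostModelError("travel_cost_per_visit must be non-negative")
        if self.hours_off_work_override is not None and self.hours_off_work_override < 0:
            raise CostModelError("hours_off_work_override must be non-negative")
        if self.override_applies_to not in APPLY_CHOICES:
            raise CostModelError(
                f"override_applies_to must be one of {APPLY_CHOICES}")

    @property
    def effective_travel_cost_per_visit(self) -> float:
        if self.travel_cost_per_visit is not None:
            return self.travel_cost_per_visit
        return self.return_distance_km * self.travel_rate_per_km

    def _hours(self, party: str) -> float:
        if (self.hours_off_work_override is not None
                and self.override_applies_to in (party, "both")):
            return self.hours_off_work_override
        return self.clinic_visit_hours + self.time_forgone_hours

    @property
    def patient_hours_per_visit(self) -> float:
        return self._hours("patients")

    @property
    def caregiver_hours_per_visit(self) -> float:
        return self._hours("caregivers")


@dataclass(frozen=True)
class CostBreakdown:
    """Itemized savings, unrounded; ``reported`` yields display figures."""

    params: CostParameters
    visits_saved_unrounded: float
    visits_saved: int
    caregiver_visits_saved: float       # unrounded: caregivers/visit x visits saved
    parking_savings: float
    travel_savings: float
    patient_productivity_savings: float
    caregiver_productivity_savings: float
    admin_savings: float

    @property
    def out_of_pocket_total(self) -> float:
        return self.parking_savings + self.travel_savings

    @property
    def productivity_total(self) -> float:
        return self.patient_productivity_savings + self.caregiver_productivity_savings

    @property
    def grand_total(self) -> float:
        return self.out_of_pocket_total + self.productivity_total + self.admin_savings

    @property
    def per_patient(self) -> float:
        return self.grand_total / self.params.n_patients

    @property
    def reported(self) -> dict:
        """Nearest-dollar display figures.

        Line items round half away from zero; the out-of-pocket category is
        rounded from its exact sum, the productivity category is the sum of
        its rounded line items, and the grand total is the sum of the three
        reported category totals (so the reported table is internally
        additive).
        """
        oop = round_half_away(self.out_of_pocket_total)
        prod = (round_half_away(self.patient_productivity_savings)
                + round_half_away(self.caregiver_productivity_savings))
        admin = round_half_away(self.admin_savings)
        grand = oop + prod + admin
        return {
            "visits_saved": self.visits_saved,
            "caregiver_visits_saved": round_half_away(self.caregiver_visits_saved),
            "parking_savings": round_half_away(self.parking_savings),
            "travel_savings": round_half_away(self.travel_savings),
            "out_of_pocket_total": oop,
            "out_of_pocket_per_patient": round_half_away(oop / self.params.n_patients),
            "patient_productivity_savings": round_half_away(self.patient_productivity_savings),
            "caregiver_productivity_savings": round_half_away(self.caregiver_productivity_savings),
            "productivity_total": prod,
            "admin_savings": admin,
            "grand_total": grand,
            "per_patient": round_half_away(grand / self.params.n_patients),
        }


def visits_saved(params: CostParameters):
    """Visits avoided: per-patient reduction times cohort size.

    Returns ``(unrounded, rounded)``; the rounded (nearest-integer, half
    away from zero) count is what every per-visit cost is applied to.
    """
    unrounded = params.visits_saved_per_patient * params.n_patients
    return unrounded, round_half_away(unrounded)


def out_of_pocket_savings(params: CostParameters):
    """Parking and return-travel savings.

    Returns ``(parking, travel, total, per_patient_reported)`` with the
    first three unrounded and the per-patient figure rounded to the dollar.
    """
    _, v = visits_saved(params)
    parking = v * params.parking_cost_per_visit
    travel = v * params.effective_travel_cost_per_visit
    total = parking + travel
    return parking, travel, total, round_half_away(
        round_half_away(total) / params.n_patients)


def productivity_savings(params: CostParameters):
    """Human-capital productivity-loss savings.

    Patient component: rounded visits saved x under-65 fraction x hours per
    visit x wage. Caregiver component: *unrounded* caregiver visits saved
    (caregivers/visit x rounded visits saved) x employed fraction x hours x
    wage. Returns ``(patient, caregiver, total)`` unrounded.
    """
    _, v = visits_saved(params)
    patient = (v * params.prop_under65
               * params.patient_hours_per_visit * params.wage_per_hour)
    caregiver_visits = params.caregivers_per_visit * v
    caregiver = (caregiver_visits * params.caregiver_employment_prop
                 * params.caregiver_hours_per_visit * params.wage_per_hour)
    return patient, caregiver, patient + caregiver


def admin_savings(params: CostParameters) -> float:
    """Booking-time savings: rounded visits saved x administrative cost per
    visit (unrounded CAD)."""
    _, v = visits_saved(params)
    return v * params.admin_cost_per_visit


def total_savings(params: CostParameters) -> CostBreakdown:
    """Assemble the full breakdown from unrounded intermediates."""
    unrounded_v, v = visits_saved(params)
    parking, travel, _, _ = out_of_pocket_savings(params)
    patient, caregiver, _ = productivity_savings(params)
    return CostBreakdown(
        params=params,
        visits_saved_unrounded=unrounded_v,
        visits_saved=v,
        caregiver_visits_saved=params.caregivers_per_visit * v,
        parking_savings=parking,
        travel_savings=travel,
        patient_productivity_savings=patient,
        caregiver_productivity_savings=caregiver,
        admin_savings=admin_savings(params),
    )


def extrapolate(breakdown: CostBreakdown, target_n_patients: float) -> float:
    """Scale the unrounded per-patient grand total to another cohort size."""
    if target_n_patients < 0:
        raise CostModelError("target_n_patients must be non-negative")
    return breakdown.per_patient * target_n_patients


# ---------------------------------------------------------------------------
# serialization

def params_to_dict(params: CostParameters) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> CostParameters:
    try:
        return CostParameters(**d)
    except TypeError as exc:
        raise CostModelError(f"bad cost-parameter field: {exc}") from exc


def load_cost_parameters(path) -> CostParameters:
    """Read CostParameters from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return params_from_dict(data)


def breakdown_to_rows(breakdown: CostBreakdown) -> list:
    """Two-column (label, CAD) rows of the reported breakdown, in the
    layout of the published base-case table."""
    rep = breakdown.reported
    p = breakdown.params
    return [
        ("Patient visits saved", rep["visits_saved"]),
        (f"Caregiver visits saved ({p.caregivers_per_visit} caregivers/visit)",
         rep["caregiver_visits_saved"]),
        (f"Parking cost savings (${p.parking_cost_per_visit:.2f}/visit)",
         rep["parking_savings"]),
        (f"Return travel cost savings (${p.effective_travel_cost_per_visit:.2f}/visit)",
         rep["travel_savings"]),
        ("Out-of-pocket cost savings per patient", rep["out_of_pocket_per_patient"]),
        ("Total out-of-pocket cost savings", rep["out_of_pocket_total"]),
        (f"Patient opportunity cost savings (${p.wage_per_hour:.2f}/hour)",
         rep["patient_productivity_savings"]),
        (f"Caregiver opportunity cost savings (${p.wage_per_hour:.2f}/hour)",
         rep["caregiver_productivity_savings"]),
        ("Total productivity loss savings", rep["productivity_total"]),
        (f"Administrative booking savings (${p.admin_cost_per_visit:.2f}/visit)",
         rep["admin_savings"]),
        ("Total savings", rep["grand_total"]),
        ("Savings per patient", rep["per_patient"]),
    ]
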