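"""Deterministic sensitivity analysis over the cost model.

Multi-way (joint best-case / worst-case) scenarios re-evaluate the full
savings model under named parameter overrides, bounding the result; a
one-way sweep varies a single field over a grid (tornado-style input).

The two packaged scenarios:

* best case — 55.5-minute clinic visit (0.925 h, forgone time unchanged at
  1.27 h), CAD 4.50 parking, 25% of caregivers employed;
* worst case — a flat 7.5 h off work for both patients and caregivers
  (replacing clinic + forgone hours), CAD 12 parking, 75% of caregivers
  employed.

Travel cost stays at base in both; evaluation is a pure function of the
merged parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .costmodel import CostBreakdown, CostModelError, CostParameters, total_savings


class ScenarioError(ValueError):
    """Unknown override key or empty scenario set."""


_VALID_KEYS = {f.name for f in dataclasses.fields(CostParameters)}


@dataclass(frozen=True)
class Scenario:
    """Named overrides on CostParameters."""

    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.overrides) - _VALID_KEYS
        if unknown:
            raise ScenarioError(
                f"scenario {self.name!r}: unknown override key(s) {sorted(unknown)}")


BEST_CASE = Scenario("best_case", {
    "parking_cost_per_visit": 4.50,
    "clinic_visit_hours": 55.5 / 60.0,
    "caregiver_employment_prop": 0.25,
})

WORST_CASE = Scenario("worst_case", {
    "parking_cost_per_visit": 12.00,
    "hours_off_work_override": 7.5,
    "override_applies_to": "both",
    "caregiver_employment_prop": 0.75,
})


def apply_scenario(base: CostParameters, scenario: Scenario) -> CostParameters:
    """Merge overrides into a new parameter set; ``base`` is untouched."""
    try:
        return dataclasses.replace(base, **scenario.overrides)
    except CostModelError as exc:
        raise ScenarioError(f"scenario {scenario.name!r}: {exc}") from exc


def evaluate_scenario(base: CostParameters, scenario: Scenario) -> CostBreakdown:
    """Full savings breakdown under the scenario's merged parameters."""
    return total_savings(apply_scenario(base, scenario))


def multiway_range(base: CostParameters, scenarios) -> tuple:
    """Evaluate every scenario; return (min, max, table).

    Min and max are over *reported* grand totals (nearest-dollar), the
    scale on which the bound is quoted; the table preserves scenario order
    as ``(name, breakdown)`` pairs.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ScenarioError("multiway_range needs at least one scenario")
    table = [(s.name, evaluate_scenario(base, s)) for s in scenarios]
    totals = [b.reported["grand_total"] for _, b in table]
    return min(totals), max(totals), table


def one_way_sweep(base: CostParameters, fieldname: str, values) -> list:
    """Grand total at each value of one field, other fields at base.

    Returns ``(value, breakdown)`` pairs in input order.
    """
    if fieldname not in _VALID_KEYS:
        raise ScenarioError(f"unknown CostParameters field {fieldname!r}")
    out = []
    for v in values:
        sc = Scenario(f"{fieldname}={v}", {fieldname: v})
        out.append((v, evaluate_scenario(base, sc)))
    return out


def scenario_from_dict(d: dict) -> Scenario:
    if "name" not in d:
        raise ScenarioError("scenario requires a 'name'")
    return Scenario(name=d["name"], overrides=dict(d.get("overrides", {})))


def load_scenarios(path) -> list:
    """Read a YAML/JSON list of scenarios (or a single mapping)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if isinstance(data, dict):
        data = [data]
    return [scenario_from_dict(d) for d in data]


def save_scenarios(scenarios, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        [{"name": s.name, "overrides": dict(s.overrides)} for s in scenarios],
        sort_keys=False))
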