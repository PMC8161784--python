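"""Patient-level domain types and a seeded synthetic cohort generator.

The evaluation compares two care pathways for newly diagnosed lung cancer:
a *traditional* sequential-referral model (each oncology specialty seen at a
separate visit) and a *multidisciplinary clinic* (MDC) in which respirology,
medical and radiation oncology consultations are consolidated into one visit.
The raw chart-review data behind the published cohort are not distributable,
so this module provides a generator that emulates the two arms' marginal
structure — arm sizes, stage and diagnosis mix, per-stage mean oncology
visits, invasive-staging uptake, caregiver counts, travel distance and age —
well enough that every downstream stage of the pipeline runs end to end.

Two generation modes are supported:

* ``calibrated=True`` (default): integer counts are allocated
  deterministically (largest-remainder apportionment, even spreads) so that
  every discrete marginal in the spec — stage counts, per-arm-per-stage mean
  visits, staging-procedure uptake proportions — is recovered *exactly*, up
  to the unavoidable rounding of a mean times an integer group size
  (at most 1/(2n) on any recovered mean).
* ``calibrated=False``: counts are sampled (shifted truncated Poisson for
  visit counts, Bernoulli for uptake flags, multinomial for categories), so
  marginals are recovered in expectation only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._util import largest_remainder, round_half_away, spread_total

ARMS = ("traditional", "mdc")
STAGES = ("1", "2", "3", "4", "undetermined")
STAGED = ("1", "2", "3", "4")
DIAGNOSES = ("NSCLC", "SCLC", "presumed_LC", "non_LC")
TREATMENTS = ("TS", "RT", "ST")
EBUS_STAGES = ("2", "3")

COHORT_COLUMNS = [
    "patient_id", "arm", "diagnosis", "stage", "oncology_visits", "biopsies",
    "staging_imaging", "ebus_performed", "return_distance_km", "caregivers",
    "age_years", "treatments",
]


class CohortError(ValueError):
    """Invalid cohort specification or degenerate cohort input."""


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: arm, diagnosis, stage and utilization fields.

    ``oncology_visits`` counts oncology visits between diagnosis and first
    treatment; ``return_distance_km`` is the round trip home-to-clinic;
    ``treatments`` holds received-treatment flags among thoracic surgery
    (TS), radiation (RT) and systemic therapy (ST).
    """

    patient_id: str
    arm: str
    diagnosis: str
    stage: str
    oncology_visits: int
    biopsies: int
    staging_imaging: int
    ebus_performed: bool
    return_distance_km: float
    caregivers: int
    age_years: float
    treatments: frozenset = frozenset()

    def __post_init__(self):
        if self.arm not in ARMS:
            raise CohortError(f"unknown arm {self.arm!r}")
        if self.diagnosis not in DIAGNOSES:
            raise CohortError(f"unknown diagnosis {self.diagnosis!r}")
        if self.stage not in STAGES:
            raise CohortError(f"unknown stage {self.stage!r}")
        for f in ("oncology_visits", "biopsies", "staging_imaging"):
            if getattr(self, f) < 0:
                raise CohortError(f"{f} must be non-negative")
        if self.ebus_performed and self.stage not in EBUS_STAGES:
            raise CohortError(
                "ebus_performed requires stage 2 or 3 (the invasive "
                "mediastinal staging population)")
        if not 1 <= self.caregivers <= 4:
            raise CohortError("caregivers must be in [1, 4]")
        if self.return_distance_km < 0:
            raise CohortError("return_distance_km must be non-negative")
        if self.age_years <= 0:
            raise CohortError("age_years must be positive")
        if not set(self.treatments) <= set(TREATMENTS):
            raise CohortError(f"unknown treatment flags {set(self.treatments) - set(TREATMENTS)}")


def _check_props(name: str, props: dict, keys: tuple) -> None:
    unknown = set(props) - set(keys)
    if unknown:
        raise CohortError(f"{name}: unknown categories {sorted(unknown)}")
    vals = list(props.values())
    if any(v < 0 or v > 1 for v in vals):
        raise CohortError(f"{name}: proportions must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-6:
        raise CohortError(f"{name}: proportions sum to {sum(vals):.6f}, not 1")


@dataclass(frozen=True)
class ArmSpec:
    """Marginal structure of one study arm.

    ``stage_visit_means`` are per-stage mean oncology visits (stages 1-4);
    ``overall_visit_mean`` is the all-patients mean including
    undetermined-stage patients, which the calibrated allocator uses to fix
    the visit total of the undetermined group. ``treatment_props`` maps
    "stage:FLAG" (flags joined by '+') to the proportion of that stage
    receiving the treatment. ``ebus_prop`` is the fraction of stage-2/3
    patients undergoing invasive mediastinal staging by EBUS-TBNA.
    """

    name: str
    n: int
    stage_props: dict
    diagnosis_props: dict
    stage_visit_means: dict
    overall_visit_mean: float
    biopsies_mean: float
    imaging_mean: float
    ebus_prop: float
    treatment_props: dict = field(default_factory=dict)
    age_mean: float = 70.0
    age_sd: float = 9.5
    under65_frac: float = 0.23
    distance_mean_km: float = 102.0
    distance_sigma: float = 0.5
    caregiver_probs: tuple = (0.80, 0.16, 0.03, 0.01)

    def __post_init__(self):
        if self.name not in ARMS:
            raise CohortError(f"unknown arm name {self.name!r}")
        if self.n <= 0:
            raise CohortError(f"{self.name}: arm size must be positive")
        _check_props(f"{self.name}.stage_props", self.stage_props, STAGES)
        _check_props(f"{self.name}.diagnosis_props", self.diagnosis_props, DIAGNOSES)
        for s, m in self.stage_visit_means.items():
            if s not in STAGED:
                raise CohortError(f"{self.name}.stage_visit_means: unknown stage {s!r}")
            if m < 1:
                raise CohortError(f"{self.name}.stage_visit_means[{s}]: mean visits must be >= 1")
        for f_ in ("overall_visit_mean",):
            if getattr(self, f_) < 1:
                raise CohortError(f"{self.name}.{f_} must be >= 1")
        for f_ in ("biopsies_mean", "imaging_mean", "distance_mean_km", "distance_sigma"):
            if getattr(self, f_) < 0:
                raise CohortError(f"{self.name}.{f_} must be non-negative")
        for f_ in ("ebus_prop", "under65_frac"):
            v = getattr(self, f_)
            if not 0 <= v <= 1:
                raise CohortError(f"{self.name}.{f_} must lie in [0, 1]")
        if self.age_mean <= 0 or self.age_sd <= 0:
            raise CohortError(f"{self.name}: age_mean and age_sd must be positive")
        if len(self.caregiver_probs) != 4:
            raise CohortError(f"{self.name}.caregiver_probs needs 4 entries (1-4 caregivers)")
        _check_props(f"{self.name}.caregiver_probs",
                     dict(zip(("1", "2", "3", "4"), self.caregiver_probs)), ("1", "2", "3", "4"))
        for key, p in self.treatment_props.items():
            stage, _, flags = key.partition(":")
            if stage not in STAGED or not set(flags.split("+")) <= set(TREATMENTS):
                raise CohortError(f"{self.name}.treatment_props: bad key {key!r}")
            if not 0 <= p <= 1:
                raise CohortError(f"{self.name}.treatment_props[{key}] must lie in [0, 1]")

    @property
    def caregiver_mean(self) -> float:
        return sum((i + 1) * p for i, p in enumerate(self.caregiver_probs))


@dataclass(frozen=True)
class CohortSpec:
    """Full two-arm cohort specification.

    ``visit_max`` caps individual visit counts (the shifted-Poisson noise
    model is truncated there, and calibrated allocation never exceeds it).
    """

    traditional: ArmSpec
    mdc: ArmSpec
    visit_max: int = 8

    def __post_init__(self):
        if self.traditional.name != "traditional" or self.mdc.name != "mdc":
            raise CohortError("arm specs must be named 'traditional' and 'mdc'")
        if self.visit_max < 1:
            raise CohortError("visit_max must be >= 1")

    @property
    def arms(self) -> tuple:
        return (self.traditional, self.mdc)


def default_spec() -> CohortSpec:
    """Two-arm spec calibrated to the published cohort marginals.

    78 traditional / 350 MDC patients; stage, diagnosis and treatment mixes
    entered as exact count fractions; per-stage mean oncology visits and
    mean biopsies / staging-imaging per patient as published; EBUS-TBNA
    uptake 3/20 vs 57/95 among stage-2/3 patients; mean return distance
    102 km; roughly 1.25 caregivers per patient (range 1-4); under-65
    fractions 0.23 and 79/350.
    """
    traditional = ArmSpec(
        name="traditional",
        n=78,
        stage_props={"1": 24 / 78, "2": 6 / 78, "3": 14 / 78, "4": 29 / 78,
                     "undetermined": 5 / 78},
        diagnosis_props={"NSCLC": 69 / 78, "SCLC": 9 / 78, "presumed_LC": 0.0,
                         "non_LC": 0.0},
        stage_visit_means={"1": 2.29, "2": 2.33, "3": 3.43, "4": 2.55},
        overall_visit_mean=2.68,
        biopsies_mean=1.32,
        imaging_mean=2.24,
        ebus_prop=3 / 20,
        treatment_props={"1:TS": 5 / 24, "1:RT": 21 / 24, "2:TS": 2 / 6,
                         "2:RT": 5 / 6, "3:ST+RT": 8 / 14, "4:ST": 11 / 29},
        age_mean=70.0,
        age_sd=9.7,
        under65_frac=0.23,
        distance_mean_km=102.0,
    )
    mdc = ArmSpec(
        name="mdc",
        n=350,
        stage_props={"1": 109 / 350, "2": 26 / 350, "3": 69 / 350,
                     "4": 143 / 350, "undetermined": 3 / 350},
        diagnosis_props={"NSCLC": 260 / 350, "SCLC": 45 / 350,
                         "presumed_LC": 45 / 350, "non_LC": 0.0},
        stage_visit_means={"1": 1.66, "2": 2.13, "3": 2.03, "4": 1.29},
        overall_visit_mean=1.62,
        biopsies_mean=1.17,
        imaging_mean=2.02,
        ebus_prop=57 / 95,
        treatment_props={"1:TS": 15 / 109, "1:RT": 84 / 109, "2:TS": 6 / 26,
                         "2:RT": 17 / 26, "3:ST+RT": 37 / 69, "4:ST": 57 / 143},
        age_mean=71.7,
        age_sd=9.1,
        under65_frac=79 / 350,
        distance_mean_km=102.0,
    )
    return CohortSpec(traditional=traditional, mdc=mdc)


# ---------------------------------------------------------------------------
# generation


def _truncnorm(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _stage_visit_totals(arm: ArmSpec, stage_counts: dict) -> dict:
    """Integer visit totals per stage; the undetermined group absorbs the
    remainder so the all-patients mean is also recovered."""
    totals = {s: round_half_away(arm.stage_visit_means[s] * stage_counts[s])
              if stage_counts[s] else 0 for s in STAGED}
    overall = round_half_away(arm.overall_visit_mean * arm.n)
    n_undet = stage_counts["undetermined"]
    undet = overall - sum(totals.values()) if n_undet else 0
    totals["undetermined"] = max(undet, n_undet)  # at least one visit each
    return totals

def _generate_arm(arm: ArmSpec, visit_max: int, rng: np.random.Generator,
                  calibrated: bool) -> list:
    prefix = "T" if arm.name == "traditional" else "M"

    if calibrated:
        stage_counts = dict(zip(STAGES, largest_remainder(
            arm.n, [arm.stage_props.get(s, 0.0) for s in STAGES])))
        diag_counts = largest_remainder(
            arm.n, [arm.diagnosis_props.get(d, 0.0) for d in DIAGNOSES])
        caregiver_counts = largest_remainder(arm.n, list(arm.caregiver_probs))
    else:
        stages_drawn = rng.choice(len(STAGES), size=arm.n,
                                  p=[arm.stage_props.get(s, 0.0) for s in STAGES])
        stage_counts = {s: int((stages_drawn == i).sum()) for i, s in enumerate(STAGES)}
        diag_counts = rng.multinomial(
            arm.n, [arm.diagnosis_props.get(d, 0.0) for d in DIAGNOSES]).tolist()
        caregiver_counts = rng.multinomial(arm.n, list(arm.caregiver_probs)).tolist()

    stages = [s for s in STAGES for _ in range(stage_counts[s])]
    diagnoses = [d for d, k in zip(DIAGNOSES, diag_counts) for _ in range(k)]
    caregivers = [c + 1 for c, k in enumerate(caregiver_counts) for _ in range(k)]

    # oncology visit counts
    visits: dict = {}
    if calibrated:
        totals = _stage_visit_totals(arm, stage_counts)
        for s in STAGES:
            if stage_counts[s]:
                visits[s] = spread_total(totals[s], stage_counts[s],
                                         minimum=1, maximum=visit_max)
    else:
        for s in STAGES:
            if not stage_counts[s]:
                continue
            mean = arm.stage_visit_means[s] if s in STAGED else arm.overall_visit_mean
            draws = 1 + rng.poisson(mean - 1.0, size=stage_counts[s])
            visits[s] = np.minimum(draws, visit_max).astype(int).tolist()

    # biopsies and staging imaging (cohort-wide means)
    if calibrated:
        biopsies = spread_total(round_half_away(arm.biopsies_mean * arm.n), arm.n)
        imaging = spread_total(round_half_away(arm.imaging_mean * arm.n), arm.n)
    else:
        biopsies = rng.poisson(arm.biopsies_mean, size=arm.n).astype(int).tolist()
        imaging = rng.poisson(arm.imaging_mean, size=arm.n).astype(int).tolist()

    # EBUS-TBNA flags among the stage-2/3 (invasive staging) population
    n_eligible = stage_counts["2"] + stage_counts["3"]
    if calibrated:
        n_ebus = round_half_away(arm.ebus_prop * n_eligible)
        ebus_eligible = [i < n_ebus for i in range(n_eligible)]
    else:
        ebus_eligible = (rng.random(n_eligible) < arm.ebus_prop).tolist()

    # treatment flags, allocated within stage
    treatment_sets: dict = {s: [set() for _ in range(stage_counts[s])] for s in STAGES}
    for key, p in arm.treatment_props.items():
        stage, _, flagstr = key.partition(":")
        flags = set(flagstr.split("+"))
        n_s = stage_counts[stage]
        if calibrated:
            k = round_half_away(p * n_s)
            chosen = range(k)
        else:
            chosen = np.flatnonzero(rng.random(n_s) < p)
        for i in chosen:
            treatment_sets[stage][i] |= flags

    # continuous covariates
    sigma = arm.distance_sigma
    mu = math.log(arm.distance_mean_km) - sigma ** 2 / 2 if arm.distance_mean_km > 0 else 0.0
    distances = rng.lognormal(mu, sigma, size=arm.n) if arm.distance_mean_km > 0 \
        else np.zeros(arm.n)
    if calibrated and distances.mean() > 0:
        distances = distances * (arm.distance_mean_km / distances.mean())

    if calibrated:
        n_under = round_half_away(arm.under65_frac * arm.n)
        ages = np.empty(arm.n)
        under_idx = rng.permutation(arm.n)[:n_under]
        under_mask = np.zeros(arm.n, dtype=bool)
        under_mask[under_idx] = True
        if n_under:
            ages[under_mask] = _truncnorm(rng, 18.0, 65.0, arm.age_mean, arm.age_sd, n_under)
        if arm.n - n_under:
            ages[~under_mask] = _truncnorm(rng, 65.0, 100.0, arm.age_mean, arm.age_sd,
                                           arm.n - n_under)
    else:
        ages = np.clip(rng.normal(arm.age_mean, arm.age_sd, size=arm.n), 18.0, 100.0)

    records = []
    i_global = 0
    i_eligible = 0
    per_stage_pos = {s: 0 for s in STAGES}
    for s in STAGES:
        for j in range(stage_counts[s]):
            ebus = False
            if s in EBUS_STAGES:
                ebus = bool(ebus_eligible[i_eligible])
                i_eligible += 1
            records.append(PatientRecord(
                patient_id=f"{prefix}{i_global + 1:04d}",
                arm=arm.name,
                diagnosis=diagnoses[i_global],
                stage=s,
                oncology_visits=int(visits[s][j]),
                biopsies=int(biopsies[i_global]),
                staging_imaging=int(imaging[i_global]),
                ebus_performed=ebus,
                return_distance_km=float(distances[i_global]),
                caregivers=int(caregivers[i_global]),
                age_years=float(ages[i_global]),
                treatments=frozenset(treatment_sets[s][per_stage_pos[s]]),
            ))
            per_stage_pos[s] += 1
            i_global += 1
    return records


def generate_cohort(spec: CohortSpec, seed: int, calibrated: bool = True) -> list:
    """Generate a two-arm synthetic cohort.

    With ``calibrated=True`` every discrete marginal of ``spec`` is
    recovered exactly up to integer rounding; with ``calibrated=False``
    marginals hold in expectation. Equal ``(spec, seed, calibrated)``
    arguments always produce identical cohorts.
    """
    rng = np.random.default_rng(seed)
    records = []
    for arm in spec.arms:
        records.extend(_generate_arm(arm, spec.visit_max, rng, calibrated))
    return records


# ---------------------------------------------------------------------------
# summaries and I/O


def summarize_cohort(cohort) -> dict:
    """Per-arm demographic summary: sizes, stage/diagnosis counts, mean age,
    mean return distance, mean caregivers and the under-65 count."""
    cohort = list(cohort)
    if not cohort:
        raise CohortError("cannot summarize an empty cohort")
    out = {}
    for arm in ARMS:
        recs = [r for r in cohort if r.arm == arm]
        if not recs:
            continue
        out[arm] = {
            "n": len(recs),
            "stage_counts": {s: sum(r.stage == s for r in recs) for s in STAGES},
            "diagnosis_counts": {d: sum(r.diagnosis == d for r in recs) for d in DIAGNOSES},
            "mean_age_years": float(np.mean([r.age_years for r in recs])),
            "mean_return_distance_km": float(np.mean([r.return_distance_km for r in recs])),
            "mean_caregivers": float(np.mean([r.caregivers for r in recs])),
            "n_under_65": sum(r.age_years < 65 for r in recs),
            "ebus_performed": sum(r.ebus_performed for r in recs),
            "ebus_eligible": sum(r.stage in EBUS_STAGES for r in recs),
        }
    return out


def cohort_to_frame(cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        d = dataclasses.asdict(r)
        d["ebus_performed"] = "true" if r.ebus_performed else "false"
        d["treatments"] = ";".join(sorted(r.treatments))
        rows.append(d)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list:
    records = []
    for row in frame.itertuples(index=False):
        treatments = frozenset(t for t in str(row.treatments).split(";")
                               if t and t != "nan")
        records.append(PatientRecord(
            patient_id=str(row.patient_id),
            arm=str(row.arm),
            diagnosis=str(row.diagnosis),
            stage=str(row.stage),
            oncology_visits=int(row.oncology_visits),
            biopsies=int(row.biopsies),
            staging_imaging=int(row.staging_imaging),
            ebus_performed=str(row.ebus_performed).lower() == "true",
            return_distance_km=float(row.return_distance_km),
            caregivers=int(row.caregivers),
            age_years=float(row.age_years),
            treatments=treatments,
        ))
    return records


def write_cohort_csv(cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list:
    frame = pd.read_csv(path, dtype={"stage": str, "treatments": str,
                                     "ebus_performed": str},
                        keep_default_na=False, float_precision="round_trip")
    return frame_to_cohort(frame)


def spec_to_dict(spec: CohortSpec) -> dict:
    d = {"visit_max": spec.visit_max}
    for arm in spec.arms:
        ad = dataclasses.asdict(arm)
        ad["caregiver_probs"] = list(arm.caregiver_probs)
        d[arm.name] = ad
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    arms = {}
    for name in ARMS:
        if name not in d:
            raise CohortError(f"cohort spec missing arm {name!r}")
        ad = dict(d[name])
        ad["name"] = name
        if "caregiver_probs" in ad:
            ad["caregiver_probs"] = tuple(ad["caregiver_probs"])
        try:
            arms[name] = ArmSpec(**ad)
        except TypeError as exc:
            raise CohortError(f"bad field in arm spec {name!r}: {exc}") from exc
    return CohortSpec(traditional=arms["traditional"], mdc=arms["mdc"],
                      visit_max=int(d.get("visit_max", 8)))


def load_cohort_spec(path) -> CohortSpec:
    """Read a CohortSpec from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return spec_from_dict(data)


def save_cohort_spec(spec: CohortSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))
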