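"""Between-arm resource-utilization comparisons.

Reproduces the utilization table of the evaluation: per-stage mean oncology
visits between diagnosis and first treatment, mean biopsies and staging
imaging per patient, uptake of invasive mediastinal staging (EBUS-TBNA)
among stage-2/3 patients, and treatment-received proportions — each with a
two-group significance test. Undetermined-stage patients are excluded from
per-stage and treatment rows.

Tests are delegated to scipy.stats: Welch's or Student's unpaired t-test
for means, chi-squared (no continuity correction) or Fisher's exact test
for 2x2 proportions, and one-way ANOVA for k-group means. The default 2x2
test switches to Fisher's exact when any expected cell count falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARMS, EBUS_STAGES, STAGED, PatientRecord  # noqa: F401

UTILIZATION_FIELDS = ("oncology_visits", "biopsies", "staging_imaging")


class UtilizationError(ValueError):
    """Empty stratum, missing arm or degenerate test input."""


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group comparison (means or proportions)."""

    groups: tuple
    values: tuple              # group means, or proportions as percentages
    difference: float          # first minus second group value
    test: str                  # welch_t | student_t | chi_squared | fisher_exact | anova
    statistic: float
    p_value: float
    n: tuple
    df: float | None = None
    counts: tuple | None = None   # (successes_a, successes_b) for proportion tests

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise UtilizationError(f"p_value {self.p_value} outside [0, 1]")


def _normalize_stage(stage) -> str:
    return str(stage)


def mean_utilization(cohort, arm: str, fieldname: str, stage_filter=None):
    """Arithmetic mean of a utilization field over one arm.

    Returns ``(mean, n)``. With a ``stage_filter`` (or implicitly for
    per-stage visit analyses) undetermined-stage records are excluded;
    without a filter the mean runs over the whole arm.
    """
    if fieldname not in UTILIZATION_FIELDS:
        raise UtilizationError(f"unknown utilization field {fieldname!r}")
    recs = [r for r in cohort if r.arm == arm]
    if stage_filter is not None:
        sf = _normalize_stage(stage_filter)
        if sf not in STAGED:
            raise UtilizationError(f"stage_filter must be one of {STAGED}, got {stage_filter!r}")
        recs = [r for r in recs if r.stage == sf]
    if not recs:
        raise UtilizationError(
            f"no qualifying records for arm={arm!r}, field={fieldname!r}, "
            f"stage={stage_filter!r}")
    values = [getattr(r, fieldname) for r in recs]
    return float(np.mean(values)), len(values)


def compare_means(values_a, values_b, method: str = "welch_t",
                  labels=("traditional", "mdc")) -> ComparisonResult:
    """Unpaired two-sample t-test (Welch by default, Student by flag)."""
    if method not in ("welch_t", "student_t"):
        raise UtilizationError(f"unknown method {method!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UtilizationError("each group needs at least 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constants: no evidence of a difference
            return ComparisonResult(groups=labels, values=(a.mean(), b.mean()),
                                    difference=0.0, test=method, statistic=0.0,
                                    p_value=1.0, n=(len(a), len(b)),
                                    df=float(len(a) + len(b) - 2))
        raise UtilizationError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=(method == "student_t"))
    return ComparisonResult(
        groups=labels, values=(float(a.mean()), float(b.mean())),
        difference=float(a.mean() - b.mean()), test=method,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n=(len(a), len(b)), df=float(res.df))


def compare_many(groups, labels=None) -> ComparisonResult:
    """One-way ANOVA over k groups (F-test of equal means)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise UtilizationError("ANOVA needs >= 2 groups with >= 2 observations each")
    f, p = stats.f_oneway(*groups)
    labels = tuple(labels) if labels else tuple(f"group{i}" for i in range(len(groups)))
    means = tuple(float(g.mean()) for g in groups)
    return ComparisonResult(groups=labels, values=means,
                            difference=float(means[0] - means[-1]), test="anova",
                            statistic=float(f), p_value=float(p),
                            n=tuple(len(g) for g in groups),
                            df=float(len(groups) - 1))


def expected_counts(successes_a, n_a, successes_b, n_b) -> np.ndarray:
    """Expected cell counts of the 2x2 table under independence."""
    table = np.array([[successes_a, n_a - successes_a],
                      [successes_b, n_b - successes_b]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    return row * col / table.sum()


def compare_proportions(successes_a: int, n_a: int, successes_b: int, n_b: int,
                        method: str | None = None, correction: bool = False,
                        labels=("traditional", "mdc")) -> ComparisonResult:
    """Two-proportion comparison on a 2x2 table.

    ``method`` is ``chi_squared`` or ``fisher_exact``; when omitted,
    chi-squared is used unless any expected cell count is below 5, in which
    case Fisher's exact test is chosen. Proportions are reported as
    percentages; ``difference`` is in percentage points.
    """
    for s, n in ((successes_a, n_a), (successes_b, n_b)):
        if n < 1:
            raise UtilizationError("group size must be >= 1")
        if not 0 <= s <= n:
            raise UtilizationError(f"successes {s} outside [0, {n}]")
    if method is None:
        method = ("fisher_exact"
                  if (expected_counts(successes_a, n_a, successes_b, n_b) < 5).any()
                  else "chi_squared")
    if method not in ("chi_squared", "fisher_exact"):
        raise UtilizationError(f"unknown method {method!r}")
    table = np.array([[successes_a, n_a - successes_a],
                      [successes_b, n_b - successes_b]])
    pa, pb = 100.0 * successes_a / n_a, 100.0 * successes_b / n_b
    if pa == pb:
        stat, p, df = 0.0, 1.0, 1.0
    elif method == "chi_squared":
        res = stats.chi2_contingency(table, correction=correction)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.dof)
    else:
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        stat, p, df = float(stat), float(p), None
    return ComparisonResult(groups=labels, values=(pa, pb), difference=pa - pb,
                            test=method, statistic=stat, p_value=min(p, 1.0),
                            n=(n_a, n_b), df=df,
                            counts=(successes_a, successes_b))


# ---------------------------------------------------------------------------
# full utilization report


@dataclass(frozen=True)
class UtilizationRow:
    section: str
    label: str
    result: ComparisonResult = field(repr=False)


def _arm_values(cohort, arm, fieldname, stage=None):
    recs = [r for r in cohort if r.arm == arm]
    if stage is not None:
        recs = [r for r in recs if r.stage == stage]
    elif fieldname == "oncology_visits":
        pass  # all-patients visit row includes undetermined-stage records
    return [getattr(r, fieldname) for r in recs]


def utilization_report(cohort, t_method: str = "welch_t") -> list:
    """Assemble the full utilization table: visit means per stage, biopsies,
    staging imaging, EBUS-TBNA uptake and treatment proportions, each with
    its two-group test. Requires both arms present; undetermined-stage
    patients are excluded from per-stage and treatment rows."""
    cohort = list(cohort)
    for arm in ARMS:
        if not any(r.arm == arm for r in cohort):
            raise UtilizationError(f"cohort is missing arm {arm!r}")

    rows = []

    def _mean_row(section, label, fieldname, stage=None):
        a = _arm_values(cohort, "traditional", fieldname, stage)
        b = _arm_values(cohort, "mdc", fieldname, stage)
        if not a or not b:
            raise UtilizationError(f"empty stratum for {label!r}")
        rows.append(UtilizationRow(section, label, compare_means(a, b, method=t_method)))

    _mean_row("oncology_visits", "All patients", "oncology_visits")
    for s in STAGED:
        _mean_row("oncology_visits", f"Stage {s} LC", "oncology_visits", stage=s)
    _mean_row("resource_utilization", "Mean biopsies per patient", "biopsies")
    _mean_row("resource_utilization", "Mean staging imaging per patient", "staging_imaging")

    def _count(arm, pred):
        return sum(1 for r in cohort if r.arm == arm and pred(r))

    ebus_a = _count("traditional", lambda r: r.ebus_performed)
    elig_a = _count("traditional", lambda r: r.stage in EBUS_STAGES)
    ebus_b = _count("mdc", lambda r: r.ebus_performed)
    elig_b = _count("mdc", lambda r: r.stage in EBUS_STAGES)
    rows.append(UtilizationRow(
        "resource_utilization",
        "Invasive mediastinal staging by EBUS-TBNA, stage 2/3 LC",
        compare_proportions(ebus_a, elig_a, ebus_b, elig_b)))

    treatment_rows = [
        ("Stage 1 LC curative TS", "1", {"TS"}),
        ("Stage 1 LC curative RT", "1", {"RT"}),
        ("Stage 2 LC curative TS", "2", {"TS"}),
        ("Stage 2 LC curative RT", "2", {"RT"}),
        ("Stage 3 ST + RT", "3", {"ST", "RT"}),
        ("Stage 4 LC receiving ST", "4", {"ST"}),
    ]
    for label, stage, flags in treatment_rows:
        n_a = _count("traditional", lambda r: r.stage == stage)
        n_b = _count("mdc", lambda r: r.stage == stage)
        s_a = _count("traditional", lambda r: r.stage == stage and flags <= r.treatments)
        s_b = _count("mdc", lambda r: r.stage == stage and flags <= r.treatments)
        if n_a == 0 or n_b == 0:
            raise UtilizationError(f"empty stratum for {label!r}")
        rows.append(UtilizationRow("treatments", label,
                                   compare_proportions(s_a, n_a, s_b, n_b)))
    return rows


def report_to_frame(rows) -> pd.DataFrame:
    """Flatten UtilizationRows to a DataFrame mirroring the table layout."""
    out = []
    for row in rows:
        r = row.result
        out.append({
            "section": row.section,
            "label": row.label,
            "traditional": r.values[0],
            "mdc": r.values[1],
            "difference": r.difference,
            "test": r.test,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "n_traditional": r.n[0],
            "n_mdc": r.n[1],
            "successes_traditional": r.counts[0] if r.counts else None,
            "successes_mdc": r.counts[1] if r.counts else None,
        })
    return pd.DataFrame(out)
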