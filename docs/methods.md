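# Methods

## Scope and model structure

`mdcecon` implements a retrospective, cohort-level economic evaluation of
clinic consolidation in lung-cancer care, from the societal perspective:
all costs count, regardless of who pays. Four computations share one
parameterization:

1. **Utilization comparison** — between-arm differences in oncology visits
   (diagnosis to first treatment), biopsies, staging imaging, invasive
   mediastinal staging uptake, and treatments received.
2. **Visit-savings cost model** — the monetized value of avoided visits,
   in three categories (out-of-pocket, productivity, administrative).
3. **Deterministic sensitivity analysis** — joint best/worst-case scenario
   evaluation and one-way sweeps of the same model.
4. **Staging threshold analysis** — incremental cost per QALY of the
   higher EBUS-TBNA uptake, against a willingness-to-pay (WTP) threshold.

The model is intentionally arithmetic rather than statistical: given unit
variables it is closed-form, and every reported figure is a deterministic
function of the parameter set. No discounting is applied (the horizon is a
22-month program window plus a 3-year linear extrapolation), and currency
conversion is out of scope — all monetary inputs are assumed to be 2019 CAD.

## Cost model

Let `v` = visits saved per patient (default **1.06**) and `n` = patients
(**350**); the rounded total `V = round_half_away(v·n)` (**371**) is the
unit count to which every per-visit cost applies.

| parameter | unit | default | rationale |
|---|---|---|---|
| `parking_cost_per_visit` | CAD/visit | 6.00 | 2 h at CAD 3/h hospital parking |
| `travel_cost_per_visit` | CAD/visit | 59.14 | mean 102 km round trip at CAD 0.58/km allowance |
| `clinic_visit_hours` | h | 1.26 | published mean clinic-visit duration |
| `time_forgone_hours` | h | 1.27 | return travel, parking, wayfinding |
| `wage_per_hour` | CAD/h | 29.55 | average hourly earnings (human-capital approach) |
| `prop_under65` | — | 0.23 | working-age fraction of patients |
| `caregivers_per_visit` | — | 1.25 | chart-review average, range 1–4 |
| `caregiver_employment_prop` | — | 0.50 | base-case employed caregiver share |
| `admin_cost_per_visit` | CAD/visit | 1.37 | ≈3 min clerk time per booking |

Components: parking `V·6.00`; travel `V·59.14`; patient productivity
`V·0.23·(1.26+1.27)·29.55`; caregiver productivity
`(1.25·V)·0.50·(1.26+1.27)·29.55`; administrative `V·1.37`. Two
conventions matter and are fixed by design:

- **Caregiver visits stay unrounded** inside the productivity formula
  (463.75, not the displayed 464): rounding first would inflate the
  caregiver component by about CAD 10.
- **`prop_under65` scales visits, not people** — it is applied as a
  fraction of the saved visits rather than an integer patient subset.

Travel can alternatively be specified as distance × rate (102 km ×
CAD 0.58/km = 59.16 CAD/visit). The per-visit default is the printed
59.14; the two differ by 2 cents per visit and the per-visit figure is
taken as canonical, with distance mode available for cohort-driven runs.

### Rounding and reporting convention

All intermediates are unrounded `float`s; only *reported* fields are
rounded, to the nearest dollar, ties away from zero. Category totals
follow one fixed convention: the **out-of-pocket** total is rounded from
its exact sum, the **productivity** total is the sum of its two rounded
line items, and the grand total is the sum of the three reported category
totals — so the reported table is internally additive while the unrounded
breakdown remains available for scaling (extrapolation uses the unrounded
per-patient grand total). Structural invariants (additivity, degree-1
homogeneity in the visit reduction, monotonicity in every unit cost) are
asserted on the unrounded values, where they hold exactly.

### Sensitivity scenarios

- **Best case**: 55.5-min clinic visit (0.925 h; forgone time unchanged),
  CAD 4.50 parking, 25% caregiver employment.
- **Worst case**: flat 7.5 h off work for both patients and caregivers
  (`hours_off_work_override` replacing clinic + forgone hours), CAD 12
  parking, 75% caregiver employment. Under this convention the worst
  case's longer clinic visit affects no monetary component — the override
  already prices the full workday.

Travel cost is held at base in both. Scenario evaluation is a pure
function of the merged parameter set; probabilistic (Monte-Carlo)
sensitivity analysis is deliberately out of scope.

## Staging threshold analysis

Arm inputs: 3/20 (traditional) and 57/95 (MDC) EBUS-TBNA procedures among
stage-2/3 patients; CAD 1577 per procedure (conscious sedation); CAD 9
parking for 50% of procedures; CAD 59.14 travel; 7.5 h forgone at
CAD 29.55/h for the under-65 fraction of procedures (1/3 and 19/57); one
caregiver per procedure (transport home) at 50% employment; **0.071
QALY/procedure** from a same-jurisdiction costing study (the alternative
literature value 0.015 is configurable, not default).

The ICER divides unrounded incremental cost by **unrounded** incremental
QALYs (4.047 − 0.213 = 3.834); the *displayed* QALY difference follows the
table presentation (per-arm QALYs rounded to 2 decimals, then subtracted,
giving 3.84). The threshold quantity is `ΔQ* = ΔC / WTP` — the QALY gain
at which the incremental spending is exactly acceptable — with
cost-effectiveness declared when `ICER ≤ WTP` and `ΔQ > 0`; a zero QALY
difference flags the ICER undefined rather than emitting a number.

Known ±4 CAD tensions exist among the published sub-items of this table
(e.g. a printed traditional out-of-pocket of 192 vs a recomputed 190.9,
and a printed MDC patient productivity of 4,207 vs a recomputed 4,210.9);
this package keeps the unrounded recomputation canonical, which matches
the published arm totals and ICER within 0.1%.

## Synthetic cohort generator

The generator emulates the *marginal* structure of the two arms — it is a
stand-in for the study cohort, not a re-creation of it.

Calibrated mode (default) is deterministic given a seed:

- stage, diagnosis and caregiver categories by **largest-remainder
  apportionment** (ties to the earliest category), so counts sum exactly;
- per-stage visit totals `round(mean × n_stage)` spread evenly (parts
  differ by ≤1, each in [1, `visit_max`=8]); the undetermined-stage group
  absorbs the remainder against `round(overall_mean × n_arm)`, so both the
  per-stage and all-patients means are recovered to within `1/(2n)`;
- EBUS flags for the first `round(p × n_eligible)` stage-2/3 patients;
  treatment flags likewise per stage (overlap between flags is not
  calibrated — only each row's marginal proportion is);
- distances lognormal (σ = 0.5) rescaled to the exact target mean; ages
  split into truncated normals below/above 65 so the under-65 count is
  exact.

Uncalibrated mode samples instead: multinomial categories, visit counts as
`1 + Poisson(mean − 1)` truncated at `visit_max` (visit counts are ≥1
integers with small means; dispersion is not published, so the Poisson
shape is a configurable stand-in), Bernoulli flags, clipped-normal ages.

What the generator does **not** emulate: within-patient correlations
(stage × diagnosis, visits × distance), visit-count dispersion, referral
timing or scheduling, and treatment-flag co-occurrence. Consequently,
passing tests demonstrate that the pipeline recovers the published *means,
counts and proportions* and that the economic conclusions follow from
them — not that the generator reproduces patient-level variability;
p-values computed on synthetic per-stage visit distributions will not
match tests run on the real dispersed data.

Defaults not derivable from published marginals, chosen once: caregiver
distribution P(1..4) = (0.80, 0.16, 0.03, 0.01) (mean 1.25, range 1–4);
lognormal distance dispersion σ = 0.5; traditional-arm under-65 fraction
0.23 and distance 102 km (unreported for that arm; neither feeds any
monetary result); ages truncated to [18, 100].

## Statistical choices

- Default two-sample test is **Welch's** t (unequal variances), with
  Student's by flag — the equal-variance assumption of the source tests is
  unstated, so the robust default is exposed alongside the classical one.
- Default 2×2 test is **chi-squared without continuity correction**,
  switching to Fisher's exact when any expected cell count is < 5; the
  correction flag is configurable. The chi-squared p-value is validated in
  the test suite against a 10,000-draw permutation (fixed-margin
  hypergeometric) null within 3 Monte-Carlo standard errors.
- One-way ANOVA over k groups is exposed as a generic comparison; no
  published figures anchor it.
- p-values are reported unadjusted; no multiple-testing correction.
- Degenerate inputs fail loudly: groups of n < 2, zero variance in both
  groups with unequal means, empty strata, missing arms and invalid
  proportions all raise typed errors rather than returning NaN.

## Problem sizes

Everything is desk-scale: cohorts of 428 records, closed-form cost
arithmetic, 10,000-draw permutation checks and ~1,000-draw randomized
invariant sweeps; the full suite runs in seconds on one CPU.

## Limitations

Health-system physician billing (unchanged between models), childcare and
meal costs are not modelled; the extrapolation is linear in patients with
no uncertainty band; the staging analysis ignores downstream consequences
(avoided surgical staging, down-staging); and the generator's independence
assumptions above mean cohort-level statistics other than the calibrated
marginals should not be read off the synthetic data.
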