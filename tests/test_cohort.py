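"""Synthetic cohort generator: calibration, determinism, validation, I/O."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdcecon import generate_cohort, summarize_cohort
from mdcecon._util import largest_remainder, spread_total
from mdcecon.cohort import (ArmSpec, CohortError, CohortSpec, PatientRecord,
                            cohort_to_frame, frame_to_cohort, read_cohort_csv,
                            spec_from_dict, spec_to_dict, write_cohort_csv)


def _mean(cohort, arm, field, stage=None):
    vals = [getattr(r, field) for r in cohort
            if r.arm == arm and (stage is None or r.stage == stage)]
    return float(np.mean(vals)), len(vals)


class TestCalibratedMarginals:
    def test_arm_sizes(self, calibrated_cohort):
        assert sum(r.arm == "traditional" for r in calibrated_cohort) == 78
        assert sum(r.arm == "mdc" for r in calibrated_cohort) == 350

    @pytest.mark.parametrize("arm,expected", [
        ("traditional", {"1": 24, "2": 6, "3": 14, "4": 29, "undetermined": 5}),
        ("mdc", {"1": 109, "2": 26, "3": 69, "4": 143, "undetermined": 3}),
    ])
    def test_stage_counts(self, calibrated_cohort, arm, expected):
        summary = summarize_cohort(calibrated_cohort)
        assert summary[arm]["stage_counts"] == expected

    def test_diagnosis_counts(self, calibrated_cohort):
        summary = summarize_cohort(calibrated_cohort)
        assert summary["mdc"]["diagnosis_counts"]["NSCLC"] == 260
        assert summary["mdc"]["diagnosis_counts"]["SCLC"] == 45
        assert summary["mdc"]["diagnosis_counts"]["presumed_LC"] == 45
        assert summary["traditional"]["diagnosis_counts"]["NSCLC"] == 69

    @pytest.mark.parametrize("arm,stage,target,n", [
        ("traditional", "1", 2.29, 24), ("traditional", "3", 3.43, 14),
        ("traditional", "4", 2.55, 29), ("mdc", "1", 1.66, 109),
        ("mdc", "2", 2.13, 26), ("mdc", "3", 2.03, 69), ("mdc", "4", 1.29, 143),
    ])
    def test_per_stage_visit_means_within_allocation_bound(
            self, calibrated_cohort, arm, stage, target, n):
        # integer allocation can move the mean by at most 1/(2n)
        mean, count = _mean(calibrated_cohort, arm, "oncology_visits", stage)
        assert count == n
        assert abs(mean - target) <= 1 / (2 * n) + 1e-12

    @pytest.mark.parametrize("arm,target,n", [
        ("traditional", 2.68, 78), ("mdc", 1.62, 350),
    ])
    def test_overall_visit_mean(self, calibrated_cohort, arm, target, n):
        mean, count = _mean(calibrated_cohort, arm, "oncology_visits")
        assert count == n
        assert abs(mean - target) <= 1 / (2 * n) + 1e-12

    def test_ebus_uptake_counts(self, calibrated_cohort):
        summary = summarize_cohort(calibrated_cohort)
        assert (summary["traditional"]["ebus_performed"],
                summary["traditional"]["ebus_eligible"]) == (3, 20)
        assert (summary["mdc"]["ebus_performed"],
                summary["mdc"]["ebus_eligible"]) == (57, 95)

    def test_under_65_count_enforced(self, calibrated_cohort):
        summary = summarize_cohort(calibrated_cohort)
        assert summary["mdc"]["n_under_65"] == 79

    def test_mean_distance_and_caregivers(self, calibrated_cohort):
        summary = summarize_cohort(calibrated_cohort)
        assert summary["mdc"]["mean_return_distance_km"] == pytest.approx(102.0)
        # largest-remainder over {1..4} with mean-1.25 target probabilities
        assert summary["mdc"]["mean_caregivers"] == pytest.approx(1.25, abs=0.01)
        assert all(1 <= r.caregivers <= 4 for r in calibrated_cohort)

    def test_treatment_proportions(self, calibrated_cohort):
        def frac(arm, stage, flags):
            recs = [r for r in calibrated_cohort if r.arm == arm and r.stage == stage]
            return sum(1 for r in recs if flags <= r.treatments), len(recs)

        assert frac("traditional", "1", {"TS"}) == (5, 24)
        assert frac("mdc", "1", {"RT"}) == (84, 109)
        assert frac("mdc", "4", {"ST"}) == (57, 143)
        assert frac("traditional", "3", {"ST", "RT"}) == (8, 14)

    def test_spec_example_stage_proportions(self):
        # rounded three-decimal proportions still allocate to the same counts
        counts = largest_remainder(350, [0.311, 0.074, 0.197, 0.409, 0.009])
        assert counts == [109, 26, 69, 143, 3]


class TestDeterminismAndNoise:
    def test_same_seed_identical(self, spec):
        a = generate_cohort(spec, seed=123)
        b = generate_cohort(spec, seed=123)
        assert a == b
        assert cohort_to_frame(a).equals(cohort_to_frame(b))

    def test_different_seed_differs(self, spec):
        a = generate_cohort(spec, seed=1)
        b = generate_cohort(spec, seed=2)
        assert a != b

    def test_uncalibrated_deterministic_per_seed(self, spec):
        a = generate_cohort(spec, seed=5, calibrated=False)
        b = generate_cohort(spec, seed=5, calibrated=False)
        assert a == b

    def test_uncalibrated_recovers_means_within_3_se(self, spec):
        """Sampled (uncalibrated) cohorts recover the spec's visit mean and
        stage-1 proportion within 3 standard errors, pooling across seeds."""
        n_seeds = 60
        visit_means, stage1 = [], []
        for seed in range(n_seeds):
            cohort = generate_cohort(spec, seed=seed, calibrated=False)
            mdc = [r for r in cohort if r.arm == "mdc"]
            visit_means.append(np.mean([r.oncology_visits for r in mdc]))
            stage1.append(sum(r.stage == "1" for r in mdc) / 350)
        # visit counts: 1 + Poisson(mean-1), variance ~ (mean-1)
        se_visits = np.sqrt(0.62 / (350 * n_seeds))
        assert abs(np.mean(visit_means) - 1.62) <= 3 * se_visits
        p = 109 / 350
        se_p = np.sqrt(p * (1 - p) / (350 * n_seeds))
        assert abs(np.mean(stage1) - p) <= 3 * se_p

    def test_visit_cap_respected(self, spec):
        for seed in range(5):
            cohort = generate_cohort(spec, seed=seed, calibrated=False)
            assert all(1 <= r.oncology_visits <= spec.visit_max for r in cohort)


class TestValidation:
    def test_unnormalized_stage_props_rejected(self, spec):
        with pytest.raises(CohortError, match="stage_props"):
            dataclasses.replace(
                spec.mdc, stage_props={"1": 0.5, "2": 0.2, "3": 0.2, "4": 0.2,
                                       "undetermined": 0.0})

    def test_negative_proportion_rejected(self, spec):
        with pytest.raises(CohortError, match="diagnosis_props"):
            dataclasses.replace(
                spec.mdc,
                diagnosis_props={"NSCLC": 1.2, "SCLC": -0.2, "presumed_LC": 0.0,
                                 "non_LC": 0.0})

    def test_nonpositive_arm_size_rejected(self, spec):
        with pytest.raises(CohortError, match="positive"):
            dataclasses.replace(spec.traditional, n=0)

    def test_ebus_outside_stage_2_3_rejected(self):
        with pytest.raises(CohortError, match="stage 2 or 3"):
            PatientRecord(patient_id="X1", arm="mdc", diagnosis="NSCLC",
                          stage="4", oncology_visits=1, biopsies=1,
                          staging_imaging=1, ebus_performed=True,
                          return_distance_km=10.0, caregivers=1, age_years=70.0)

    def test_caregiver_range_enforced(self):
        with pytest.raises(CohortError, match="caregivers"):
            PatientRecord(patient_id="X1", arm="mdc", diagnosis="NSCLC",
                          stage="1", oncology_visits=1, biopsies=0,
                          staging_imaging=0, ebus_performed=False,
                          return_distance_km=10.0, caregivers=5, age_years=70.0)

    def test_empty_cohort_summary_fails(self):
        with pytest.raises(CohortError, match="empty"):
            summarize_cohort([])


class TestSummaryAndIO:
    def test_single_patient_summary(self):
        rec = PatientRecord(patient_id="M0001", arm="mdc", diagnosis="NSCLC",
                            stage="1", oncology_visits=2, biopsies=1,
                            staging_imaging=2, ebus_performed=False,
                            return_distance_km=102.0, caregivers=2,
                            age_years=70.0, treatments=frozenset({"RT"}))
        s = summarize_cohort([rec])["mdc"]
        assert s["n"] == 1
        assert s["mean_return_distance_km"] == 102.0
        assert s["mean_caregivers"] == 2.0
        assert sum(s["stage_counts"].values()) == 1

    def test_mean_distance_is_arithmetic_mean(self):
        recs = [PatientRecord(patient_id=f"M{i}", arm="mdc", diagnosis="NSCLC",
                              stage="1", oncology_visits=1, biopsies=0,
                              staging_imaging=0, ebus_performed=False,
                              return_distance_km=d, caregivers=1, age_years=70.0)
                for i, d in enumerate((100.0, 102.0, 104.0))]
        assert summarize_cohort(recs)["mdc"]["mean_return_distance_km"] == 102.0

    def test_csv_round_trip(self, calibrated_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(calibrated_cohort, path)
        again = read_cohort_csv(path)
        assert again == calibrated_cohort
        header = path.read_text().splitlines()[0]
        assert header == ("patient_id,arm,diagnosis,stage,oncology_visits,"
                          "biopsies,staging_imaging,ebus_performed,"
                          "return_distance_km,caregivers,age_years,treatments")

    def test_frame_round_trip(self, calibrated_cohort):
        assert frame_to_cohort(cohort_to_frame(calibrated_cohort)) == calibrated_cohort

    def test_spec_dict_round_trip(self, spec):
        assert spec_from_dict(spec_to_dict(spec)) == spec

    def test_packaged_default_spec_matches_code(self, spec):
        from mdcecon.cohort import load_cohort_spec
        from mdcecon.datafiles import packaged_path
        assert load_cohort_spec(packaged_path("default_cohort.yaml")) == spec


class TestAllocationPrimitives:
    @given(st.integers(0, 500),
           st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_largest_remainder_sums_to_n(self, n, weights):
        total = sum(weights)
        props = [w / total for w in weights]
        counts = largest_remainder(n, props)
        assert sum(counts) == n
        assert all(c >= 0 for c in counts)
        # never off by more than one unit from the exact quota
        assert all(abs(c - n * p) < 1 for c, p in zip(counts, props))

    @given(st.integers(1, 50), st.integers(0, 400))
    @settings(max_examples=200, deadline=None)
    def test_spread_total_even_and_exact(self, k, total):
        parts = spread_total(total, k)
        assert sum(parts) == total
        assert max(parts) - min(parts) <= 1

    def test_spread_total_infeasible(self):
        with pytest.raises(ValueError):
            spread_total(3, 5, minimum=1)
        with pytest.raises(ValueError):
            spread_total(50, 5, maximum=8)

    def test_stage4_mdc_allocation_matches_enumeration_oracle(self):
        # brute check: target sum for 143 patients at mean 1.29 is 184
        total = round(1.29 * 143)
        parts = spread_total(total, 143, minimum=1, maximum=8)
        assert sum(parts) == total == 184
        assert abs(np.mean(parts) - 1.29) <= 1 / (2 * 143)
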