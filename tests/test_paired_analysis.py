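"""Tumour-normal delta records and cohort pattern classification."""

import numpy as np
import pytest

from nc886.epigenotyping import EpigenotypeCall, classify_cohort
from nc886.paired_analysis import (
    DeltaRecord,
    PatternRules,
    categorize_deltas,
    classify_pattern,
    compute_paired_deltas,
    deltas_to_frame,
    group_mean_difference,
    pattern_report,
)
from nc886.synthetic_data import ShiftSpec, generate_paired_cohort, make_config


def _paired(cfg, n, spec, seed):
    normal, tumour, truth = generate_paired_cohort(cfg, n, spec, seed=seed)
    pairs = {p: (f"{p}_N", f"{p}_T") for p in truth.index}
    return normal, tumour, truth, pairs


class TestComputePairedDeltas:
    def test_sign_convention_and_categories(self, make_matrix):
        normal = make_matrix({"N1": [0.50] * 11, "N2": [0.50] * 11})
        tumour = make_matrix({"T1": [0.40] * 11, "T2": [0.505] * 11})
        records, n_excl = compute_paired_deltas(
            normal, tumour, {"P1": ("N1", "T1"), "P2": ("N2", "T2")}
        )
        by_pair = {r.pair_id: r for r in records}
        assert by_pair["P1"].delta == pytest.approx(-0.10)
        assert by_pair["P1"].category == "hypomethylated"
        assert by_pair["P2"].delta == pytest.approx(0.005)
        assert by_pair["P2"].category == "stable"
        assert n_excl == 0

    def test_unknown_sample_id_is_an_error_naming_it(self, make_matrix):
        normal = make_matrix({"N1": [0.5] * 11})
        tumour = make_matrix({"T1": [0.5] * 11})
        with pytest.raises(KeyError, match="NX"):
            compute_paired_deltas(normal, tumour, {"P1": ("NX", "T1")})

    def test_pairs_with_missing_summaries_excluded_and_counted(self, make_matrix):
        normal = make_matrix({"N1": [0.5] * 11, "N2": [0.5, 0.5]})
        tumour = make_matrix({"T1": [0.4] * 11, "T2": [0.4] * 11})
        records, n_excl = compute_paired_deltas(
            normal, tumour, {"P1": ("N1", "T1"), "P2": ("N2", "T2")}, min_probes=3
        )
        assert len(records) == 1 and n_excl == 1

    def test_invariant_to_pair_ordering(self, make_matrix):
        normal = make_matrix({"N1": [0.5] * 11, "N2": [0.3] * 11})
        tumour = make_matrix({"T1": [0.4] * 11, "T2": [0.35] * 11})
        pairs = {"P1": ("N1", "T1"), "P2": ("N2", "T2")}
        rev = dict(reversed(pairs.items()))
        r1 = {r.pair_id: r.delta for r in compute_paired_deltas(normal, tumour, pairs)[0]}
        r2 = {r.pair_id: r.delta for r in compute_paired_deltas(normal, tumour, rev)[0]}
        assert r1 == r2

    def test_renal_carcinoma_split_recovered_exactly_at_zero_noise(self):
        """30/46 hypo beyond -0.02 and 6/46 hyper beyond +0.02 recovered exactly."""
        cfg = make_config("blood", probe_noise_sd=0.0)
        spec = ShiftSpec(frac_hypo=30 / 46, frac_stable=10 / 46, frac_hyper=6 / 46)
        normal, tumour, truth, pairs = _paired(cfg, 46, spec, seed=47)
        records, _ = compute_paired_deltas(normal, tumour, pairs)
        fractions, counts = categorize_deltas(records)
        assert counts == {"hypomethylated": 30, "stable": 10, "hypermethylated": 6}
        assert fractions["hypomethylated"] == pytest.approx(30 / 46)
        assert fractions["hypermethylated"] == pytest.approx(6 / 46)
        assert fractions["stable"] == pytest.approx(10 / 46)
        recovered = {r.pair_id: r.category for r in records}
        assert recovered == truth["shift_category"].to_dict()

    def test_recovery_above_99_percent_with_probe_noise(self):
        cfg = make_config("blood", probe_noise_sd=0.005)
        spec = ShiftSpec(
            frac_hypo=0.5,
            frac_stable=0.2,
            frac_hyper=0.3,
            hypo_magnitude=(0.05, 0.3),
            hyper_magnitude=(0.05, 0.2),
        )
        normal, tumour, truth, pairs = _paired(cfg, 1000, spec, seed=53)
        records, _ = compute_paired_deltas(normal, tumour, pairs)
        recovered = {r.pair_id: r.category for r in records}
        agree = np.mean([recovered[p] == truth.loc[p, "shift_category"] for p in truth.index])
        assert agree >= 0.99


class TestCategorizeDeltas:
    def test_all_zero_deltas_are_stable(self):
        records = [DeltaRecord(f"P{i}", 0.5, 0.5, 0.0, "stable") for i in range(5)]
        fractions, _ = categorize_deltas(records)
        assert fractions == {"hypomethylated": 0.0, "stable": 1.0, "hypermethylated": 0.0}

    def test_zero_threshold_keeps_only_exact_zeros_stable(self):
        records = [
            DeltaRecord("P1", 0.5, 0.5, 0.0, "stable"),
            DeltaRecord("P2", 0.5, 0.501, 0.001, "stable"),
            DeltaRecord("P3", 0.5, 0.499, -0.001, "stable"),
        ]
        fractions, counts = categorize_deltas(records, threshold=0.0)
        assert counts == {"hypomethylated": 1, "stable": 1, "hypermethylated": 1}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(59)
        records = [
            DeltaRecord(f"P{i}", 0.5, 0.5 + d, d, "stable")
            for i, d in enumerate(rng.normal(0, 0.05, 200))
        ]
        fractions, _ = categorize_deltas(records)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            categorize_deltas([])


class TestGroupMeanDifference:
    def test_four_of_six_non_methylated_controls_reach_03(self):
        betas = {f"case{i}": 0.50 for i in range(6)}
        betas |= {f"ctrl{i}": 0.03 for i in range(4)}
        betas |= {"ctrl4": 0.50, "ctrl5": 0.50}
        labels = {k: ("case" if k.startswith("case") else "ctrl") for k in betas}
        delta = group_mean_difference(betas, labels)
        assert delta == pytest.approx(0.31333, abs=0.0001)
        assert delta >= 0.3

    def test_identical_groups_give_zero(self):
        betas = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5}
        labels = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        assert group_mean_difference(betas, labels) == 0.0

    def test_swapping_labels_flips_sign(self):
        betas = {"a": 0.5, "b": 0.1}
        labels = {"a": "g1", "b": "g2"}
        flipped = {"a": "g2", "b": "g1"}
        assert group_mean_difference(betas, labels) == pytest.approx(
            -group_mean_difference(betas, flipped)
        )

    def test_one_group_only_is_an_error(self):
        with pytest.raises(ValueError):
            group_mean_difference({"a": 0.5, "b": 0.3}, {"a": "g1", "b": "g1"})


def _calls_from_fractions(fractions: dict[str, float], n: int = 200):
    betas = {"non_methylated": 0.03, "intermediate": 0.30, "imprinted": 0.50, "over_methylated": 0.70}
    calls = []
    i = 0
    for cat, frac in fractions.items():
        for _ in range(round(frac * n)):
            calls.append(EpigenotypeCall(f"S{i}", betas[cat], 11, cat))
            i += 1
    return calls


class TestPatternReport:
    def test_blood_like_cohort_is_bimodal_maintained(self):
        calls = _calls_from_fractions(
            {"imprinted": 0.75, "non_methylated": 0.24, "intermediate": 0.01}
        )
        report = pattern_report(calls, reference="blood")
        assert report.pattern_class == "bimodal_maintained"

    def test_over_methylated_cohort_is_hypermethylation_shift(self):
        calls = _calls_from_fractions(
            {"over_methylated": 0.70, "imprinted": 0.20, "non_methylated": 0.10}
        )
        report = pattern_report(calls, reference="blood")
        assert report.pattern_class == "hypermethylation_shift"

    def test_spread_cohort_with_large_outside_fraction_is_pattern_lost(self):
        calls = _calls_from_fractions(
            {
                "imprinted": 0.35,
                "non_methylated": 0.30,
                "intermediate": 0.20,
                "over_methylated": 0.15,
            }
        )
        report = pattern_report(calls, reference="blood")
        assert report.outside_fraction == pytest.approx(0.35)
        assert report.pattern_class == "pattern_lost"

    def test_unimodal_reference_yields_unimodal_baseline(self):
        calls = _calls_from_fractions({"imprinted": 1.0})
        report = pattern_report(calls, reference="skeletal_muscle")
        assert report.pattern_class == "unimodal_baseline"

    def test_class_is_pure_function_of_emitted_fractions(self):
        calls = _calls_from_fractions(
            {"imprinted": 0.6, "non_methylated": 0.2, "intermediate": 0.2}
        )
        report = pattern_report(calls, reference="blood")
        re_evaluated = classify_pattern(report.fractions, make_config("blood"), PatternRules())
        assert re_evaluated == report.pattern_class

    def test_too_few_samples_is_an_error(self):
        calls = _calls_from_fractions({"imprinted": 1.0}, n=5)
        with pytest.raises(ValueError, match="raw category fractions"):
            pattern_report(calls, reference="blood")

    def test_synthetic_blood_cohort_classified_as_maintained(self, blood_config):
        from nc886.synthetic_data import generate_cohort

        matrix, _, _ = generate_cohort(blood_config, 500, seed=61)
        calls, _ = classify_cohort(matrix)
        assert pattern_report(calls, reference="blood").pattern_class == "bimodal_maintained"


def test_deltas_to_frame_roundtrips_fields():
    records = [DeltaRecord("P1", 0.5, 0.4, -0.1, "hypomethylated")]
    frame = deltas_to_frame(records)
    assert list(frame.columns) == ["pair_id", "normal_beta", "tumour_beta", "delta", "category"]
    assert frame.iloc[0]["delta"] == -0.1
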