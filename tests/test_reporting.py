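"""Concordance, kit and depth comparisons, proportions."""

import math
import random

import numpy as np
import pytest

from ionaudit.error_classifier import ClassifiedVariant
from ionaudit.io_formats import GenomicLocus, VariantCall
from ionaudit.reporting import (
    correction_concordance,
    depth_comparison,
    kit_comparison,
    low_coverage_report,
    proportions_report,
    singleton_correction,
)
from ionaudit.synthetic_data import KITS, TruthSpec, simulate_cohort


def call(pos, sample, ref="A", alt="G"):
    return VariantCall(sample, GenomicLocus("chr1", pos), ref=ref, alt=alt)


class TestConcordance:
    def test_identical_sets_nothing_corrected(self):
        calls = [call(100 + i, f"s{j}") for i in range(20) for j in range(3)]
        table = correction_concordance(calls, list(calls))
        assert table.corrected == 0
        assert table.retained == 20

    def test_bins_sum_to_total_flagged(self):
        rng = random.Random(2)
        flagged = []
        for i in range(60):
            for j in range(rng.randint(1, 5)):
                flagged.append(call(1000 + i, f"s{j:02d}"))
        secondary = [c for c in flagged if rng.random() < 0.5]
        table = correction_concordance(flagged, secondary)
        assert sum(b["primary"] for b in table.bins.values()) == table.total == 60

    def test_random_deletions_match_membership_scan_oracle(self):
        rng = random.Random(17)
        flagged = []
        by_key = {}
        for i in range(80):
            carriers = [f"s{j:02d}" for j in range(rng.randint(1, 6))]
            for s in carriers:
                flagged.append(call(500 + i, s))
            by_key[("chr1", 500 + i, "A", "G")] = set(carriers)
        secondary = [c for c in flagged if rng.random() < 0.4]
        sec_keys = {}
        for c in secondary:
            sec_keys.setdefault(c.key, set()).add(c.sample_id)
        table = correction_concordance(flagged, secondary)
        oracle_corrected = sum(
            1 for k, carriers in by_key.items() if not (carriers & sec_keys.get(k, set()))
        )
        assert table.corrected == oracle_corrected
        # per-sample mode counts calls, not loci
        per_sample = correction_concordance(flagged, secondary, per_sample=True)
        assert per_sample.total == len(flagged)
        assert per_sample.retained == len(secondary)

    def test_singletons(self):
        flagged = [call(1, "s01"), call(2, "s01"), call(3, "s01"), call(3, "s02")]
        secondary = [call(2, "s01")]
        res = singleton_correction(flagged, secondary)
        assert res["n_singletons"] == 2
        assert res["corrected"] == 1
        assert res["corrected_percent"] == 50.0

    def test_no_singletons(self):
        flagged = [call(1, "s01"), call(1, "s02")]
        res = singleton_correction(flagged, [])
        assert res["n_singletons"] == 0 and res["corrected"] == 0


class TestKitComparison:
    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_identical_groups(self):
        df = kit_comparison({"SNV": {"S200V3": [5, 6, 7], "HiQ": [5, 6, 7]}})
        row = df.iloc[0]
        assert row.t == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)
        assert row.mean_a == row.mean_b

    def test_closed_form_t_statistic(self):
        # (1,2,3) vs (4,5,6): pooled s^2 = 1, t = -3/sqrt(2/3), df = 4
        df = kit_comparison({"x": {"A": [1, 2, 3], "B": [4, 5, 6]}})
        row = df.iloc[0]
        expected_t = (2 - 5) / math.sqrt(1 * (1 / 3 + 1 / 3))
        assert row.t == pytest.approx(expected_t)
        from scipy import stats

        expected_p = 2 * stats.t.sf(abs(expected_t), df=4)
        assert row.p == pytest.approx(expected_p)

    def test_swapping_groups_negates_t(self):
        a = {"x": {"A": [1, 2, 3, 4], "B": [2, 4, 6, 9]}}
        b = {"x": {"A": [2, 4, 6, 9], "B": [1, 2, 3, 4]}}
        ta = kit_comparison(a).iloc[0]
        # group order is sorted by kit name, so relabel to force the swap
        swapped = {"x": {"C": a["x"]["B"], "D": a["x"]["A"]}}
        tb = kit_comparison(swapped).iloc[0]
        assert tb.t == pytest.approx(-ta.t)
        assert tb.p == pytest.approx(ta.p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            kit_comparison({"x": {"A": [1], "B": [2, 3]}})

    def test_synthetic_kit_difference_direction(self):
        """With kit-profile-driven injection, HiQ samples carry fewer
        homopolymer-indel errors per sample than S200V3 samples."""
        assert (
            KITS["HiQ"].homopolymer_indels_per_sample
            < KITS["S200V3"].homopolymer_indels_per_sample
        )
        cohort = simulate_cohort(
            TruthSpec(n_common_true=0, n_ultrarare_true=0, n_noncds_decoy=0,
                      n_norsid_decoy=0, n_sex_decoy=0),
            n_samples=8, seed=5, kit_scaled=True,
        )
        indel_counts = {s: 0.0 for s in cohort.per_sample_calls}
        for t in cohort.truth:
            if t.mechanism == "HOMOPOLYMER_INDEL":
                indel_counts[t.sample_ids[0]] += 1
        groups = {"INDEL": {"S200V3": [], "HiQ": []}}
        for s, kit in cohort.kit_assignment.items():
            groups["INDEL"][kit].append(indel_counts[s])
        df = kit_comparison(groups)
        row = df.iloc[0]
        means = {row.kit_a: row.mean_a, row.kit_b: row.mean_b}
        assert means["HiQ"] < means["S200V3"]


class TestDepthComparison:
    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_all_equal_depths(self):
        res = depth_comparison(
            {"HLFP": {"A": [50.0] * 5, "B": [50.0] * 5},
             "clean": {"A": [50.0] * 5, "B": [50.0] * 5}}
        )
        s = res["summary"]
        assert s["HLFP"]["A"]["mean"] == s["clean"]["B"]["mean"] == 50.0
        assert s["HLFP"]["A"]["sd"] == 0.0

    def test_constructed_shift_recovers_ordering(self):
        rng = np.random.default_rng(3)
        res = depth_comparison(
            {
                "HLFP": {"A": rng.normal(60, 5, 40), "B": rng.normal(60, 5, 40)},
                "error_prone": {"A": rng.normal(80, 5, 40), "B": rng.normal(80, 5, 40)},
                "clean": {"A": rng.normal(120, 5, 40), "B": rng.normal(120, 5, 40)},
            }
        )
        s = res["summary"]
        assert s["HLFP"]["A"]["mean"] < s["error_prone"]["A"]["mean"] < s["clean"]["A"]["mean"]
        assert res["class_tests"]["HLFP_vs_clean"]["p"] < 0.001

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_hand_mean_sd(self):
        res = depth_comparison({"x": {"A": [1.0, 2.0, 3.0], "B": [2.0, 2.0]}})
        assert res["summary"]["x"]["A"]["mean"] == pytest.approx(2.0)
        assert res["summary"]["x"]["A"]["sd"] == pytest.approx(1.0)
        assert res["summary"]["x"]["B"]["sd"] == pytest.approx(0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            depth_comparison({"x": {"A": []}})


class TestProportions:
    @staticmethod
    def _cv(pos, types, sample="s01"):
        return ClassifiedVariant(call(pos, sample), frozenset(types), {})

    def test_random_labels_match_tabulation_oracle(self):
        rng = random.Random(11)
        types = ["SIMPLICITY", "SNV_CLUSTER", "PERIPHERAL", "BASE_INVERSION"]
        classified = []
        consensus = {}
        for i in range(300):
            labels = rng.sample(types, rng.randint(0, 2))
            classified.append(self._cv(1000 + i, labels))
            consensus[("chr1", 1000 + i, "A", "G")] = rng.choice(["HLFP", "LFP", "LTP"])
        rep = proportions_report(classified, consensus)
        hlfp_keys = {k for k, v in consensus.items() if v == "HLFP"}
        by_key = {cv.call.key: cv.error_types for cv in classified}
        for t in types:
            oracle = sum(1 for k in hlfp_keys if t in by_key[k])
            assert rep["type_counts"][t] == oracle
        assert rep["multi_label"] == sum(1 for k in hlfp_keys if len(by_key[k]) >= 2)
        assert (
            rep["single_label"] + rep["multi_label"] + rep["unlabeled"] == rep["n_hlfp"]
        )

    def test_all_clean_fixture_is_all_zero(self):
        classified = [self._cv(10 + i, []) for i in range(5)]
        consensus = {("chr1", 10 + i, "A", "G"): "HLFP" for i in range(5)}
        rep = proportions_report(classified, consensus)
        assert all(v == 0 for v in rep["type_counts"].values())
        assert rep["unlabeled"] == 5

    def test_multi_labels_push_percent_sum_over_100(self):
        classified = [self._cv(1, ["SIMPLICITY", "SNV_CLUSTER"]), self._cv(2, ["SIMPLICITY"])]
        consensus = {("chr1", 1, "A", "G"): "HLFP", ("chr1", 2, "A", "G"): "HLFP"}
        rep = proportions_report(classified, consensus)
        assert sum(rep["type_percent"].values()) > 100.0


class TestLowCoverage:
    def test_shared_and_per_kit_counts(self):
        depth = {
            ("chr1", 100): {"S200V3": 3.0, "HiQ": 4.0},
            ("chr1", 200): {"S200V3": 2.0, "HiQ": 80.0},
            ("chr1", 300): {"S200V3": 90.0, "HiQ": 85.0},
        }
        rep = low_coverage_report(depth)
        assert rep["n_low"] == 2
        assert rep["per_kit"] == {"HiQ": 1, "S200V3": 2}
        assert rep["shared"] == 1
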