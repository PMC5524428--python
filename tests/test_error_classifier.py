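"""The four error-pattern classifiers: rules, boundaries, oracles,
and truth recovery on synthetic cohorts."""

import itertools
import random

import pytest

from ionaudit.config import AuditConfig
from ionaudit.error_classifier import (
    classify_base_inversion,
    classify_cohort,
    classify_peripheral,
    classify_simplicity,
    classify_variant,
    ClassificationContext,
    detect_snv_clusters,
    supporting_reads,
)
from ionaudit.io_formats import AlignedRead, GenomicLocus, ReadEvent, VariantCall
from ionaudit.locus_filter import call_identity


def snv(pos, ref="A", alt="G", sample="s01", chrom="chr1"):
    return VariantCall(sample, GenomicLocus(chrom, pos), ref=ref, alt=alt)


def match_read(rid, start, length=50, strand="+", chrom="chr1"):
    return AlignedRead(rid, chrom, start, strand, (ReadEvent("match", length),), "A" * length)


def snv_read(rid, start, var_pos, alt="G", length=50, strand="+", chrom="chr1"):
    a = var_pos - start
    b = length - a - 1
    return AlignedRead(
        rid, chrom, start, strand,
        (ReadEvent("match", a), ReadEvent("mismatch", 1, alt), ReadEvent("match", b)),
        "A" * a + alt + "A" * b,
    )


class TestSupportingReads:
    def test_mismatch_matching_alt_included(self):
        call = snv(120)
        reads = [snv_read("alt", 100, 120), match_read("ref", 100)]
        assert [r.read_id for r in supporting_reads(call, reads)] == ["alt"]

    def test_wrong_alt_base_excluded(self):
        call = snv(120, alt="G")
        reads = [snv_read("t", 100, 120, alt="T")]
        assert supporting_reads(call, reads) == []

    def test_simulated_alt_fraction_recovered(self):
        rng = random.Random(1)
        call = snv(200)
        reads = []
        alt_ids = set()
        for i in range(50):
            start = 200 - rng.randint(5, 40)
            if i < 20:
                reads.append(snv_read(f"a{i}", start, 200))
                alt_ids.add(f"a{i}")
            else:
                reads.append(match_read(f"m{i}", start))
        got = {r.read_id for r in supporting_reads(call, reads)}
        assert got == alt_ids

    def test_deletion_and_insertion_support(self):
        del_call = VariantCall("s", GenomicLocus("chr1", 100), ref="AT", alt="A")
        del_read = AlignedRead(
            "d", "chr1", 90, "+",
            (ReadEvent("match", 11), ReadEvent("delete", 1), ReadEvent("match", 10)),
            "A" * 21,
        )
        assert supporting_reads(del_call, [del_read]) == [del_read]
        ins_call = VariantCall("s", GenomicLocus("chr1", 100), ref="A", alt="AC")
        ins_read = AlignedRead(
            "i", "chr1", 90, "+",
            (ReadEvent("match", 11), ReadEvent("insert", 1, "C"), ReadEvent("match", 10)),
            "A" * 11 + "C" + "A" * 10,
        )
        assert supporting_reads(ins_call, [ins_read]) == [ins_read]
        # deletion of the wrong length does not support
        assert supporting_reads(del_call, [ins_read]) == []


class TestSimplicity:
    def test_homopolymer_run_flagged_via_whr(self):
        ref = {"chr1": "ACGTC" + "T" * 10 + "ACGTCAGTCA"}
        flagged, ev = classify_simplicity(snv(10, ref="T", alt="C"), ref)
        assert flagged and ev["whr_rich"]

    def test_shuffled_window_not_flagged(self):
        ref = {"chr1": "ACGTGACTGTCAGTACGAT"}
        flagged, ev = classify_simplicity(snv(10, ref="T", alt="C"), ref)
        assert not flagged
        assert ev["whr"] <= 2.22

    def test_dinucleotide_repeat_flagged_below_whr_threshold(self):
        ref = {"chr1": "CAG" + "AT" * 6 + "GCAG"}
        call = snv(10, ref="T", alt="G")
        flagged, ev = classify_simplicity(call, ref)
        assert flagged
        assert not ev["whr_rich"] and ev["dinucleotide_repeat"]


def oracle_cluster_flags(calls, min_snvs=3, span=50):
    """Exhaustive all-subsets oracle: a call is flagged iff some subset of
    >= min_snvs same-chromosome SNVs containing it spans <= span."""
    flags = []
    snvs = [i for i, c in enumerate(calls) if c.variant_class == "SNV"]
    for i, c in enumerate(calls):
        hit = False
        if i in snvs:
            peers = [j for j in snvs if calls[j].locus.chrom == c.locus.chrom]
            for k in range(min_snvs, len(peers) + 1):
                for combo in itertools.combinations(peers, k):
                    if i not in combo:
                        continue
                    pos = [calls[j].locus.pos for j in combo]
                    if max(pos) - min(pos) + 1 <= span:
                        hit = True
                        break
                if hit:
                    break
        flags.append(hit)
    return flags


class TestSnvCluster:
    def test_span_exactly_fifty_flags_all(self):
        calls = [snv(100), snv(120), snv(149)]
        assert [f.flagged for f in detect_snv_clusters(calls)] == [True] * 3
        assert detect_snv_clusters(calls)[0].span == 50

    def test_span_fifty_one_flags_none(self):
        calls = [snv(100), snv(120), snv(150)]
        assert [f.flagged for f in detect_snv_clusters(calls)] == [False] * 3

    def test_outlier_not_dragged_in(self):
        calls = [snv(10), snv(20), snv(30), snv(90)]
        assert [f.flagged for f in detect_snv_clusters(calls)] == [True, True, True, False]

    def test_indels_neither_flagged_nor_counted(self):
        calls = [snv(10), snv(20), VariantCall("s01", GenomicLocus("chr1", 30), ref="AT", alt="A")]
        assert [f.flagged for f in detect_snv_clusters(calls)] == [False] * 3

    def test_matches_exhaustive_subset_oracle(self):
        rng = random.Random(21)
        for _ in range(150):
            n = rng.randint(1, 12)
            calls = []
            for _ in range(n):
                if rng.random() < 0.85:
                    calls.append(snv(rng.randint(1, 160), chrom=rng.choice(["chr1", "chr2"])))
                else:
                    calls.append(
                        VariantCall("s01", GenomicLocus("chr1", rng.randint(1, 160)),
                                    ref="AT", alt="A")
                    )
            got = [f.flagged for f in detect_snv_clusters(calls)]
            assert got == oracle_cluster_flags(calls)


class TestPeripheral:
    def test_all_supporting_reads_near_end(self):
        call = snv(100)
        reads = [snv_read(f"r{i}", 98, 100) for i in range(10)]  # offset 3
        flagged, ev = classify_peripheral(call, reads)
        assert flagged and ev["peripheral_fraction"] == 1.0

    def test_offset_six_not_peripheral(self):
        call = snv(100)
        (flagged, ev) = classify_peripheral(call, [snv_read("r", 95, 100)])  # offset 6
        assert not flagged and ev["peripheral_fraction"] == 0.0

    def test_offset_five_is_peripheral_inclusive(self):
        call = snv(100)
        flagged, _ = classify_peripheral(call, [snv_read("r", 96, 100)])  # offset 5
        assert flagged

    def test_half_peripheral_below_default_fraction(self):
        call = snv(100)
        reads = [snv_read(f"p{i}", 98, 100) for i in range(5)] + [
            snv_read(f"m{i}", 80, 100) for i in range(5)
        ]
        flagged, ev = classify_peripheral(call, reads)
        assert not flagged and ev["peripheral_fraction"] == 0.5

    def test_no_support_is_false_with_reason(self):
        flagged, ev = classify_peripheral(snv(100), [match_read("r", 90)])
        assert not flagged and ev["reason"] == "no support"

    def test_soft_clips_do_not_shift_terminus(self):
        # aligned start is 98 regardless of the 4 clipped bases
        read = AlignedRead(
            "c", "chr1", 98, "+",
            (ReadEvent("clip", 4, "AAAA"), ReadEvent("match", 2),
             ReadEvent("mismatch", 1, "G"), ReadEvent("match", 47)),
            "AAAA" + "AA" + "G" + "A" * 47,
        )
        flagged, _ = classify_peripheral(snv(100), [read])
        assert flagged

    def test_monotone_in_margin_antitone_in_fraction(self):
        rng = random.Random(8)
        call = snv(300)
        reads = [
            snv_read(f"r{i}", 300 - rng.randint(0, 30), 300, length=40) for i in range(12)
        ]
        prev = False
        for margin in range(1, 40):
            cur, _ = classify_peripheral(call, reads, margin=margin, fraction=0.6)
            assert cur or not prev  # once true, stays true as margin grows
            prev = cur
        prev = True
        for fraction in [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]:
            cur, _ = classify_peripheral(call, reads, margin=5, fraction=fraction)
            assert prev or not cur  # once false, stays false as fraction grows
            prev = cur


class TestBaseInversion:
    def test_cg_to_gc_adjacent_snvs(self):
        calls = [snv(100, ref="C", alt="G"), snv(101, ref="G", alt="C")]
        flags = classify_base_inversion(calls)
        assert all(f.flagged for f in flags)
        assert flags[0].relation == "reversal"

    def test_cg_to_gc_single_mnv(self):
        calls = [VariantCall("s", GenomicLocus("chr1", 100), ref="CG", alt="GC")]
        assert classify_base_inversion(calls)[0].flagged

    def test_agc_to_cag_rotation(self):
        calls = [VariantCall("s", GenomicLocus("chr1", 100), ref="AGC", alt="CAG")]
        (flag,) = classify_base_inversion(calls)
        assert flag.flagged and flag.relation == "rotation"

    def test_aa_to_cc_not_inversion(self):
        calls = [snv(100, ref="A", alt="C"), snv(101, ref="A", alt="C")]
        assert not any(f.flagged for f in classify_base_inversion(calls))

    def test_paired_del_ins_within_span(self):
        calls = [
            VariantCall("s", GenomicLocus("chr1", 100), ref="TC", alt="T"),
            VariantCall("s", GenomicLocus("chr1", 103), ref="A", alt="AC"),
        ]
        flags = classify_base_inversion(calls)
        assert all(f.flagged for f in flags)
        assert flags[0].relation == "del_ins_pair"
        assert flags[0].partners == (("chr1", 103),)

    def test_paired_del_ins_beyond_span_not_flagged(self):
        calls = [
            VariantCall("s", GenomicLocus("chr1", 100), ref="TC", alt="T"),
            VariantCall("s", GenomicLocus("chr1", 106), ref="A", alt="AC"),
        ]
        assert not any(f.flagged for f in classify_base_inversion(calls))

    def test_del_ins_of_different_strings_not_flagged(self):
        calls = [
            VariantCall("s", GenomicLocus("chr1", 100), ref="TC", alt="T"),
            VariantCall("s", GenomicLocus("chr1", 103), ref="A", alt="AG"),
        ]
        assert not any(f.flagged for f in classify_base_inversion(calls))

    def test_non_adjacent_snvs_not_grouped(self):
        calls = [snv(100, ref="C", alt="G"), snv(103, ref="G", alt="C")]
        assert not any(f.flagged for f in classify_base_inversion(calls))


class TestClassifyVariant:
    def test_multi_label_union(self):
        # SNV inside an AT repeat with two companions within 50 bp
        ref = {"chr1": "GACGC" + "AT" * 7 + "ATGCG" + "ACGT" * 20}
        call = snv(12, ref="T", alt="G")
        companions = [snv(30, ref="C", alt="T"), snv(50, ref="G", alt="A")]
        ctx = ClassificationContext(
            reference=ref, sample_calls=[call] + companions, reads=[]
        )
        cv = classify_variant(call, ctx)
        assert cv.error_types == {"SIMPLICITY", "SNV_CLUSTER"}

    def test_clean_variant_empty_set(self, small_cohort):
        truth = {t.locus_key: t for t in small_cohort.truth}
        classified = classify_cohort(
            small_cohort.per_sample_calls,
            small_cohort.reads_by_sample,
            small_cohort.reference,
            candidate_keys=small_cohort.candidate_keys(),
        )
        clean = [
            cv for cv in classified
            if truth[call_identity(cv.call)].mechanism == "TRUE_VARIANT"
        ]
        assert clean and all(cv.error_types == frozenset() for cv in clean)

    def test_noise_free_recovery_is_exact(self, small_cohort):
        """Every injected mechanism is recovered by exactly its intended
        classifier; clean loci are never flagged."""
        truth = {t.locus_key: t for t in small_cohort.truth}
        classified = classify_cohort(
            small_cohort.per_sample_calls,
            small_cohort.reads_by_sample,
            small_cohort.reference,
            candidate_keys=small_cohort.candidate_keys(),
        )
        assert len(classified) == len(small_cohort.candidate_keys())
        for cv in classified:
            expected = truth[call_identity(cv.call)].expected_types
            assert cv.error_types == expected, (cv.call, cv.evidence)

    def test_config_thresholds_respected(self):
        ref = {"chr1": "ACGTGACTGTCAGTACGAT" + "ACGT" * 30}
        call = snv(10, ref="T", alt="C")
        companions = [snv(40, ref="A", alt="G"), snv(80, ref="A", alt="G")]
        loose = AuditConfig(cluster_span=100)
        ctx = ClassificationContext(ref, [call] + companions, [], loose)
        assert "SNV_CLUSTER" in classify_variant(call, ctx).error_types
        strict = AuditConfig(cluster_span=50)
        ctx = ClassificationContext(ref, [call] + companions, [], strict)
        assert "SNV_CLUSTER" not in classify_variant(call, ctx).error_types
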