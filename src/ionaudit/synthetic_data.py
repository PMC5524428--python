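"""Synthetic cohorts with known truth for every stage of the audit.

The generator emulates the statistical *structure* of an exome cohort
sequenced on a semiconductor platform — per-sample call sets, aligned
reads, population-catalogue stand-ins, and two raters' verdicts — without
modelling flow-signal physics: error mechanisms are injected directly as
their alignment-level consequences, which is what the classifiers consume.

Each injected locus sits in a designed 25-bp sequence context planted in
its own reference tile, so the 19-bp complexity window of every call (and
of the partner calls of paired insertion/deletion inversions) lies fully
inside designed sequence:

* homopolymer windows (a 9-bp T run): WHR ≈ 8.3, well above 2.22;
* dinucleotide windows ((AT)7): WHR = 1 but copolymer-flagged — the
  simplicity sub-population *below* the WHR threshold;
* neutral windows: WHR ≈ 1, no flags.

Mechanisms map to the labels they must trigger; under noise-free settings
every injected locus is recovered by exactly its intended classifier(s)
and clean loci are never flagged.  All outputs are deterministic functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import FP, TP
from .locus_filter import call_identity
from .io_formats import (
    AlignedRead,
    GenomicLocus,
    ReadEvent,
    Region,
    SiteTable,
    VariantCall,
    write_fasta,
    write_sam,
    write_site_table,
    write_vcf,
)

__all__ = [
    "KitProfile",
    "S200V3",
    "HIQ",
    "TruthSpec",
    "RaterFixtureSpec",
    "SyntheticTruth",
    "CohortData",
    "make_reference",
    "simulate_cohort",
    "make_rater_fixture",
    "make_classification_fixture",
    "PAPER_STRUCTURE",
]

TILE = 160  # bp per planted feature tile
_CTX_OFFSET = 60  # tile offset of the designed 25-mer
_ANCHOR = 12  # anchor offset inside the designed 25-mer
READ_LEN = 70

# Designed 25-mers.  The 19-bp window of any call anchored at offsets
# 11..14 stays inside the designed sequence.
_CTX = {
    # 9-bp T run; anchor inside the run; WHR of the 19-bp window = 91/11
    "homopolymer": "GACGATCAGCTTTTTTTTTCAGCGA",
    # (AT)7 copolymer; all runs length 1 so WHR = 1, dinucleotide-flagged
    "dinucleotide": "GACGCATATATATATATATGCGACG",
    # no runs >2, no repeat, balanced composition
    "neutral": "TCAACGTCAGTCGATCGACTGACGT",
    # neutral with 'CG' at anchor offsets 12..13 (reversal target)
    "inversion_cg": "TCAACGTCAGTCCGATCGACTGACT",
    # neutral with 'AGC' at anchor offsets 12..14 (rotation target)
    "inversion_agc": "TCAACGTCAGTCAGCATCGACTGAC",
}


@dataclass(frozen=True)
class KitProfile:
    """Directional error/coverage profile of a sequencing chemistry.

    Absolute per-sample counts are synthetic defaults; only their
    direction (the newer HiQ chemistry produces fewer homopolymer and
    base-inversion indel errors and better coverage than S200V3) mirrors
    reported behaviour.
    """

    name: str
    homopolymer_indels_per_sample: int
    clustered_snvs_per_sample: int
    end_of_read_per_sample: int
    inversions_per_sample: int
    depth_mean: float
    depth_sd: float


S200V3 = KitProfile("S200V3", 5, 4, 2, 3, depth_mean=100.0, depth_sd=15.0)
HIQ = KitProfile("HiQ", 2, 4, 2, 1, depth_mean=115.0, depth_sd=15.0)
KITS = {"S200V3": S200V3, "HiQ": HIQ}


@dataclass
class TruthSpec:
    """Mechanism counts for one simulated cohort (whole-cohort loci)."""

    n_common_true: int = 30  # in population catalogues -> filtered out
    n_ultrarare_true: int = 10  # rsID but absent from catalogues
    n_homopolymer_indel: int = 8
    n_dinucleotide_snv: int = 0  # simplicity via copolymer flag (WHR = 1)
    n_simplicity_cluster: int = 0  # multi-label: simplicity + SNV cluster
    n_clustered_snv: int = 8
    n_end_of_read: int = 6
    n_inversion_mnv: int = 4
    n_inversion_delins_pairs: int = 1  # each pair contributes two loci
    n_low_coverage: int = 0
    n_noncds_decoy: int = 8
    n_norsid_decoy: int = 8
    n_sex_decoy: int = 4

    def n_candidate_loci(self) -> int:
        """Loci the filter cascade should retain (ultrarare true + errors)."""
        return (
            self.n_ultrarare_true
            + self.n_homopolymer_indel
            + self.n_dinucleotide_snv
            + self.n_simplicity_cluster
            + self.n_clustered_snv
            + self.n_end_of_read
            + self.n_inversion_mnv
            + 2 * self.n_inversion_delins_pairs
            + self.n_low_coverage
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one injected locus."""

    locus_key: tuple  # (chrom, pos, ref, alt), normalised
    mechanism: str
    expected_types: frozenset
    sample_ids: tuple
    rsid: Optional[str]
    context_kind: str


@dataclass
class CohortData:
    """Everything one simulated cohort produces, in memory."""

    reference: dict[str, str]
    features: pd.DataFrame
    per_sample_calls: dict[str, list[VariantCall]]
    reads_by_sample: dict[str, list[AlignedRead]]
    truth: list[SyntheticTruth]
    dbsnp: SiteTable
    t1gp: SiteTable
    exac: SiteTable
    cds_regions: list[Region]
    kit_assignment: dict[str, str]

    def candidate_keys(self) -> set:
        return {t.locus_key for t in self.truth if t.mechanism not in _FILTERED_MECHANISMS}

    def write(self, outdir: str | Path) -> Path:
        """Emit the cohort as plain-text files (FASTA/SAM/VCF/TSV/BED)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "ref.fa")
        lengths = {c: len(s) for c, s in self.reference.items()}
        for sample in sorted(self.per_sample_calls):
            calls = sorted(
                self.per_sample_calls[sample], key=lambda c: (c.locus.chrom, c.locus.pos)
            )
            write_vcf(calls, outdir / f"{sample}.vcf", contig_lengths=lengths)
            write_sam(
                self.reads_by_sample.get(sample, []),
                outdir / f"{sample}.sam",
                contig_lengths=lengths,
            )
        for name, table in (("dbsnp", self.dbsnp), ("t1gp", self.t1gp), ("exac", self.exac)):
            write_site_table(
                sorted((k[0], k[1], k[2], k[3], table.frequency(k)) for k in table.keys),
                outdir / f"{name}.tsv",
            )
        with open(outdir / "cds.bed", "w") as fh:
            for r in sorted(self.cds_regions):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
        pd.DataFrame(
            [
                {
                    "chrom": t.locus_key[0],
                    "pos": t.locus_key[1],
                    "ref": t.locus_key[2],
                    "alt": t.locus_key[3],
                    "mechanism": t.mechanism,
                    "expected_types": ";".join(sorted(t.expected_types)),
                    "samples": ";".join(t.sample_ids),
                    "rsid": t.rsid or ".",
                }
                for t in self.truth
            ]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.kit_assignment.items()), columns=["sample", "kit"]
        ).to_csv(outdir / "kits.tsv", sep="\t", index=False)
        return outdir


_FILTERED_MECHANISMS = {"COMMON_TRUE", "NONCDS_DECOY", "NORSID_DECOY", "SEX_DECOY"}

_MECHANISM_LABELS = {
    "TRUE_VARIANT": frozenset(),
    "HOMOPOLYMER_INDEL": frozenset({"SIMPLICITY"}),
    "COPOLYMER_SNV": frozenset({"SIMPLICITY"}),
    "COPOLYMER_CLUSTERED_SNV": frozenset({"SIMPLICITY", "SNV_CLUSTER"}),
    "CLUSTERED_SNV": frozenset({"SNV_CLUSTER"}),
    "END_OF_READ": frozenset({"PERIPHERAL"}),
    "BASE_INVERSION": frozenset({"BASE_INVERSION"}),
    "LOW_COVERAGE": frozenset(),
    "COMMON_TRUE": frozenset(),
    "NONCDS_DECOY": frozenset(),
    "NORSID_DECOY": frozenset(),
    "SEX_DECOY": frozenset(),
}


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_reference(
    feature_spec: Sequence[tuple[str, str, int]],
    seed: int,
    tile: int = TILE,
    min_length: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build a tiled reference with planted sequence contexts.

    ``feature_spec`` is a sequence of (chrom, kind, count) with kind one
    of the designed contexts.  Each feature gets its own ``tile`` bp, the
    designed 25-mer embedded at a fixed offset in otherwise random
    sequence; the returned table records (feature_id, chrom, kind,
    anchor) with ``anchor`` the 1-based position a variant should be
    anchored at.  Contigs are padded to at least ``min_length``.
    """
    per_chrom: dict[str, list[tuple[str, int]]] = {}
    for chrom, kind, count in feature_spec:
        if kind not in _CTX:
            raise ValueError(f"unknown context kind {kind!r}")
        if count < 0:
            raise ValueError("feature count must be >= 0")
        per_chrom.setdefault(chrom, []).extend([(kind, i) for i in range(count)])
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    rows = []
    fid = 0
    for chrom in sorted(per_chrom):
        kinds = per_chrom[chrom]
        parts: list[str] = []
        for tile_idx, (kind, _) in enumerate(kinds):
            ctx = _CTX[kind]
            left = _random_flank(rng, _CTX_OFFSET)
            right = _random_flank(rng, tile - _CTX_OFFSET - len(ctx))
            parts.append(left + ctx + right)
            anchor = tile_idx * tile + _CTX_OFFSET + _ANCHOR + 1  # 1-based
            rows.append({"feature_id": fid, "chrom": chrom, "kind": kind, "anchor": anchor})
            fid += 1
        seq = "".join(parts)
        if len(seq) < min_length:
            seq += _random_flank(rng, min_length - len(seq))
        reference[chrom] = seq
    return reference, pd.DataFrame(rows, columns=["feature_id", "chrom", "kind", "anchor"])


# ---------------------------------------------------------------------------
# read construction


def _ref_read(ref: str, chrom: str, start: int, rid: str, strand: str) -> AlignedRead:
    seq = ref[start - 1 : start - 1 + READ_LEN]
    return AlignedRead(rid, chrom, start, strand, (ReadEvent("match", len(seq)),), seq)


def _alt_read(
    ref: str, chrom: str, start: int, rid: str, strand: str, call: VariantCall
) -> AlignedRead:
    """A READ_LEN-footprint read expressing the call's ALT."""
    pos = call.locus.pos
    vclass = call.variant_class
    end = start + READ_LEN - 1
    events: list[ReadEvent] = []
    seq = ""
    if vclass in ("SNV", "MNV"):
        a = pos - start
        b = end - (pos + len(call.ref) - 1)
        events = [
            ReadEvent("match", a),
            ReadEvent("mismatch", len(call.alt), call.alt),
            ReadEvent("match", b),
        ]
        seq = ref[start - 1 : pos - 1] + call.alt + ref[pos + len(call.ref) - 1 : end]
    elif vclass == "DEL":
        ndel = len(call.ref) - len(call.alt)
        del_start = pos + len(call.alt)
        a = del_start - start
        b = end - (del_start + ndel - 1)
        events = [ReadEvent("match", a), ReadEvent("delete", ndel), ReadEvent("match", b)]
        seq = ref[start - 1 : del_start - 1] + ref[del_start + ndel - 1 : end]
    else:  # INS
        inserted = call.alt[len(call.ref) :]
        a = pos - start + 1
        events = [
            ReadEvent("match", a),
            ReadEvent("insert", len(inserted), inserted),
            ReadEvent("match", end - pos),
        ]
        seq = ref[start - 1 : pos] + inserted + ref[pos:end]
    events = [e for e in events if e.length > 0]
    return AlignedRead(rid, chrom, start, strand, tuple(events), seq)


def _delins_read(
    ref: str, chrom: str, start: int, rid: str, strand: str, del_call: VariantCall,
    ins_call: VariantCall,
) -> AlignedRead:
    """Read carrying both halves of a misaligned inversion: one deleted
    base and the same base inserted a few positions downstream."""
    dpos, ipos = del_call.locus.pos, ins_call.locus.pos
    inserted = ins_call.alt[len(ins_call.ref) :]
    del_start = dpos + 1
    end = start + READ_LEN - 1
    events = [
        ReadEvent("match", del_start - start),
        ReadEvent("delete", 1),
        ReadEvent("match", ipos - del_start),
        ReadEvent("insert", len(inserted), inserted),
        ReadEvent("match", end - ipos),
    ]
    seq = (
        ref[start - 1 : del_start - 1]
        + ref[del_start : ipos]
        + inserted
        + ref[ipos:end]
    )
    return AlignedRead(rid, chrom, start, strand, tuple(events), seq)


def _reads_for_locus(
    ref: str,
    calls: Sequence[VariantCall],
    rid_base: str,
    peripheral: bool = False,
    n_alt: int = 6,
    n_ref: int = 4,
    delins: bool = False,
) -> list[AlignedRead]:
    """Supporting + reference reads around one locus.

    Mid-read placement puts the variant ~35 bp from either end; peripheral
    placement puts it 3 aligned bases from the start or end, alternating.
    """
    chrom = calls[0].locus.chrom
    pos = calls[0].locus.pos
    reads: list[AlignedRead] = []
    for i in range(n_alt):
        strand = "+" if i % 2 == 0 else "-"
        if peripheral:
            start = pos - 2 if i % 2 == 0 else pos - (READ_LEN - 3)
        else:
            start = pos - 34 + (i % 3)
        rid = f"{rid_base}_alt{i}"
        if delins:
            reads.append(_delins_read(ref, chrom, start, rid, strand, calls[0], calls[1]))
        else:
            reads.append(_alt_read(ref, chrom, start, rid, strand, calls[0]))
    for i in range(n_ref):
        strand = "+" if i % 2 == 0 else "-"
        reads.append(_ref_read(ref, chrom, pos - 30 - i, f"{rid_base}_ref{i}", strand))
    return reads


# ---------------------------------------------------------------------------
# cohort simulation


def _metrics(rng: np.random.Generator, kit: KitProfile, low_coverage: bool = False) -> dict:
    depth = 3 if low_coverage else max(10, int(rng.normal(kit.depth_mean, kit.depth_sd)))
    return {
        "AF": round(float(rng.uniform(0.3, 0.6)), 3),
        "QUAL": round(float(rng.uniform(30, 90)), 1),
        "DP": float(depth),
        "SB": round(float(rng.uniform(0.4, 0.6)), 3),
    }


def simulate_cohort(
    truth_spec: TruthSpec,
    n_samples: int = 6,
    kit_assignment: Optional[Mapping[str, str]] = None,
    seed: int = 17,
    reference: Optional[tuple[dict[str, str], pd.DataFrame]] = None,
    kit_scaled: bool = False,
) -> CohortData:
    """Simulate a multi-sample exome-like cohort with injected errors.

    True variants are drawn as common (present in both population-table
    stand-ins, with rsIDs) or ultrarare-true (rsID but absent from the
    tables).  Injected error loci always receive rsIDs and never appear
    in the population tables, so the filter cascade retains exactly the
    ultrarare-true and error loci.  Each injected locus is carried by one
    sample (round-robin); companion SNVs that complete a cluster are
    planted without dbSNP membership so they never become candidates
    themselves.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    spec = truth_spec
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    if kit_assignment is None:
        half = (n_samples + 1) // 2
        kit_assignment = {s: ("S200V3" if i < half else "HiQ") for i, s in enumerate(samples)}
    else:
        kit_assignment = dict(kit_assignment)
        samples = sorted(kit_assignment)
        n_samples = len(samples)

    # (mechanism, context kind, chrom, fixed sample or None) per planted locus
    plan: list[tuple[str, str, str, Optional[str]]] = []

    def add(mech: str, kind: str, chrom: str, count: int, sample: Optional[str] = None):
        plan.extend([(mech, kind, chrom, sample)] * count)

    add("COMMON_TRUE", "neutral", "chr1", spec.n_common_true)
    add("TRUE_VARIANT", "neutral", "chr1", spec.n_ultrarare_true)
    if kit_scaled:
        # per-sample error counts come from the kit profiles (with ±1
        # sampling jitter), so the two chemistries differ in the
        # direction the profiles encode
        jitter_rng = np.random.default_rng(seed + 2)
        for s in samples:
            kit = KITS[kit_assignment[s]]
            def jittered(base: int) -> int:
                return max(0, base + int(jitter_rng.integers(-1, 2)))
            add("HOMOPOLYMER_INDEL", "homopolymer", "chr1",
                jittered(kit.homopolymer_indels_per_sample), s)
            add("CLUSTERED_SNV", "neutral", "chr1",
                jittered(kit.clustered_snvs_per_sample), s)
            add("END_OF_READ", "neutral", "chr1",
                jittered(kit.end_of_read_per_sample), s)
            add("BASE_INVERSION", "inversion_cg", "chr1",
                jittered(kit.inversions_per_sample), s)
    else:
        add("HOMOPOLYMER_INDEL", "homopolymer", "chr1", spec.n_homopolymer_indel)
        add("COPOLYMER_SNV", "dinucleotide", "chr1", spec.n_dinucleotide_snv)
        add("COPOLYMER_CLUSTERED_SNV", "dinucleotide", "chr1", spec.n_simplicity_cluster)
        add("CLUSTERED_SNV", "neutral", "chr1", spec.n_clustered_snv)
        add("END_OF_READ", "neutral", "chr1", spec.n_end_of_read)
        n_cg = (spec.n_inversion_mnv + 1) // 2
        add("BASE_INVERSION", "inversion_cg", "chr1", n_cg)
        add("BASE_INVERSION", "inversion_agc", "chr1", spec.n_inversion_mnv - n_cg)
        add("BASE_INVERSION_DELINS", "neutral", "chr1", spec.n_inversion_delins_pairs)
    add("LOW_COVERAGE", "neutral", "chr1", spec.n_low_coverage)
    add("NONCDS_DECOY", "neutral", "chr1", spec.n_noncds_decoy)
    add("NORSID_DECOY", "neutral", "chr1", spec.n_norsid_decoy)
    add("SEX_DECOY", "neutral", "chrX", spec.n_sex_decoy)

    if reference is None:
        counts: dict[tuple[str, str], int] = {}
        for mech, kind, chrom, _sample in plan:
            counts[(chrom, kind)] = counts.get((chrom, kind), 0) + 1
        # features laid out per chromosome in plan order
        feature_spec = []
        seen: set[tuple[str, str]] = set()
        for mech, kind, chrom, _sample in plan:
            if (chrom, kind) not in seen:
                seen.add((chrom, kind))
                feature_spec.append((chrom, kind, counts[(chrom, kind)]))
        ref, features = make_reference(feature_spec, seed=seed)
    else:
        ref, features = reference

    # hand out features by (chrom, kind) in order
    pools: dict[tuple[str, str], list[int]] = {}
    for row in features.itertuples(index=False):
        pools.setdefault((row.chrom, row.kind), []).append(int(row.anchor))
    cursors: dict[tuple[str, str], int] = {k: 0 for k in pools}

    def next_anchor(chrom: str, kind: str) -> int:
        key = (chrom, kind)
        if cursors.get(key, 0) >= len(pools.get(key, ())):
            raise ValueError(f"feature spec exhausted for {key}; reference too small")
        anchor = pools[key][cursors[key]]
        cursors[key] += 1
        return anchor

    rng = np.random.default_rng(seed + 1)
    per_sample_calls: dict[str, list[VariantCall]] = {s: [] for s in samples}
    reads_by_sample: dict[str, list[AlignedRead]] = {s: [] for s in samples}
    truth: list[SyntheticTruth] = []
    dbsnp_rows: list[tuple] = []
    t1gp_rows: list[tuple] = []
    exac_rows: list[tuple] = []
    cds: list[Region] = []
    noncds_anchors: set[tuple[str, int]] = set()
    rs_counter = 100000

    def new_rsid() -> str:
        nonlocal rs_counter
        rs_counter += 1
        return f"rs{rs_counter}"

    for li, (mech, kind, chrom, fixed_sample) in enumerate(plan):
        anchor = next_anchor(chrom, kind)
        sample = fixed_sample if fixed_sample is not None else samples[li % n_samples]
        kit = KITS[kit_assignment[sample]]
        contig = ref[chrom]
        low = mech == "LOW_COVERAGE"
        rsid = None if mech == "NORSID_DECOY" else new_rsid()
        locus = GenomicLocus(chrom, anchor)
        companion_calls: list[VariantCall] = []
        want_reads = mech not in _FILTERED_MECHANISMS

        if mech == "HOMOPOLYMER_INDEL":
            # delete one base of the T run (anchored representation)
            call = VariantCall(
                sample, locus, ref=contig[anchor - 1 : anchor + 1], alt=contig[anchor - 1],
                rsid=rsid, metrics=_metrics(rng, kit),
            )
            audited = [call]
        elif mech in ("COPOLYMER_SNV", "COPOLYMER_CLUSTERED_SNV", "CLUSTERED_SNV",
                      "END_OF_READ", "TRUE_VARIANT", "COMMON_TRUE", "LOW_COVERAGE",
                      "NONCDS_DECOY", "NORSID_DECOY", "SEX_DECOY"):
            refb = contig[anchor - 1]
            altb = {"A": "G", "C": "T", "G": "A", "T": "C"}[refb]
            call = VariantCall(sample, locus, ref=refb, alt=altb, rsid=rsid,
                               metrics=_metrics(rng, kit, low))
            audited = [call]
            if mech in ("COPOLYMER_CLUSTERED_SNV", "CLUSTERED_SNV"):
                for off in (-20, 20):
                    cpos = anchor + off
                    crefb = contig[cpos - 1]
                    caltb = {"A": "G", "C": "T", "G": "A", "T": "C"}[crefb]
                    companion_calls.append(
                        VariantCall(sample, GenomicLocus(chrom, cpos), ref=crefb, alt=caltb,
                                    rsid=None, metrics=_metrics(rng, kit))
                    )
        elif mech == "BASE_INVERSION":
            if kind == "inversion_cg":
                call = VariantCall(sample, locus, ref="CG", alt="GC", rsid=rsid,
                                   metrics=_metrics(rng, kit))
            else:
                call = VariantCall(sample, locus, ref="AGC", alt="CAG", rsid=rsid,
                                   metrics=_metrics(rng, kit))
            audited = [call]
        elif mech == "BASE_INVERSION_DELINS":
            # the misaligned form: delete a base, reinsert it 3 bp away
            dpos = anchor - 1
            ipos = anchor + 2
            moved = contig[dpos]  # 0-based: the base after the del anchor
            del_call = VariantCall(
                sample, GenomicLocus(chrom, dpos),
                ref=contig[dpos - 1] + moved, alt=contig[dpos - 1],
                rsid=rsid, metrics=_metrics(rng, kit),
            )
            ins_call = VariantCall(
                sample, GenomicLocus(chrom, ipos),
                ref=contig[ipos - 1], alt=contig[ipos - 1] + moved,
                rsid=new_rsid(), metrics=_metrics(rng, kit),
            )
            audited = [del_call, ins_call]
        else:
            raise AssertionError(mech)

        per_sample_calls[sample].extend(audited + companion_calls)
        if want_reads:
            n_alt, n_ref = (1, 1) if low else (6, 4)
            reads_by_sample[sample].extend(
                _reads_for_locus(
                    contig,
                    audited,
                    rid_base=f"{sample}_L{li}",
                    peripheral=(mech == "END_OF_READ"),
                    n_alt=n_alt,
                    n_ref=n_ref,
                    delins=(mech == "BASE_INVERSION_DELINS"),
                )
            )

        mech_name = "BASE_INVERSION" if mech == "BASE_INVERSION_DELINS" else mech
        for call in audited:
            key = call_identity(call)
            truth.append(
                SyntheticTruth(
                    locus_key=key,
                    mechanism=mech_name,
                    expected_types=_MECHANISM_LABELS[mech_name],
                    sample_ids=(sample,),
                    rsid=call.rsid,
                    context_kind=kind,
                )
            )
            if mech != "NORSID_DECOY":
                dbsnp_rows.append((key[0], key[1], key[2], key[3], None))
            if mech == "COMMON_TRUE":
                af = round(float(rng.uniform(0.05, 0.4)), 3)
                if li % 3 != 0:
                    t1gp_rows.append((key[0], key[1], key[2], key[3], af))
                else:
                    exac_rows.append((key[0], key[1], key[2], key[3], af))
        if mech == "NONCDS_DECOY":
            noncds_anchors.add((chrom, anchor))

    # CDS regions: one per tile except the non-CDS decoy tiles
    for row in features.itertuples(index=False):
        a = int(row.anchor)
        if (row.chrom, a) in noncds_anchors:
            continue
        cds.append(Region(row.chrom, max(0, a - 80), a + 80))

    return CohortData(
        reference=ref,
        features=features,
        per_sample_calls=per_sample_calls,
        reads_by_sample=reads_by_sample,
        truth=truth,
        dbsnp=SiteTable(dbsnp_rows),
        t1gp=SiteTable(t1gp_rows),
        exac=SiteTable(exac_rows),
        cds_regions=cds,
        kit_assignment=kit_assignment,
    )


# ---------------------------------------------------------------------------
# rater / count-structure fixtures


@dataclass(frozen=True)
class RaterFixtureSpec:
    """Count structure for the packaged curation/concordance fixture.

    The default mirrors the printed structure of the audited cohort:
    675 candidate loci splitting 393/126/156 into HLFP/LFP/LTP; HLFP
    error-type totals 219/172/22/19 with 39 double-labelled loci; 519
    flagged (HLFP+LFP) variants of which 201 are corrected by the
    secondary caller; 170 singletons of which 85 are corrected; 27
    variants carried by every one of the 27 samples, 5 of them corrected.
    """

    n_hlfp: int = 393
    n_lfp: int = 126
    n_ltp: int = 156
    simplicity: int = 219
    snv_cluster: int = 172
    peripheral: int = 22
    base_inversion: int = 19
    multi_label: int = 39  # all double-labelled simplicity+cluster
    whr_rich_simplicity: int = 158
    n_corrected: int = 201
    n_singletons: int = 170
    singleton_corrected: int = 85
    n_samples: int = 27
    n_all_sample_variants: int = 27
    all_sample_corrected: int = 5

    @property
    def n_loci(self) -> int:
        return self.n_hlfp + self.n_lfp + self.n_ltp

    @property
    def n_flagged(self) -> int:
        return self.n_hlfp + self.n_lfp

    def validate(self) -> None:
        total_labels = self.simplicity + self.snv_cluster + self.peripheral + self.base_inversion
        if total_labels != self.n_hlfp + self.multi_label:
            raise ValueError(
                "label totals inconsistent: per-type counts must sum to "
                "n_hlfp + multi_label (each multi-label locus carries 2 labels)"
            )
        if self.multi_label > min(self.simplicity, self.snv_cluster):
            raise ValueError("multi-label count exceeds a contributing type")
        if not (0 <= self.whr_rich_simplicity <= self.simplicity - self.multi_label):
            raise ValueError(
                "whr_rich_simplicity must fit within the simplicity-only loci"
            )
        mid = self.n_flagged - self.n_singletons - self.n_all_sample_variants
        mid_corrected = self.n_corrected - self.singleton_corrected - self.all_sample_corrected
        if mid < 0 or not (0 <= mid_corrected <= mid):
            raise ValueError("concordance counts inconsistent")
        if self.singleton_corrected > self.n_singletons:
            raise ValueError("singleton_corrected exceeds n_singletons")
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples")


PAPER_STRUCTURE = RaterFixtureSpec()


def make_rater_fixture(spec: RaterFixtureSpec = PAPER_STRUCTURE):
    """Explicit two-rater verdict tables plus the flagged/secondary call
    sets realising ``spec``.

    Returns ``(verdicts_a, verdicts_b, loci, flagged_calls,
    secondary_calls)``: verdict dicts keyed by locus key; ``loci`` the
    ordered locus list; the call lists feed the concordance operations.
    Discordant loci alternate which rater says FP.
    """
    spec.validate()
    loci = [("chr1", 10_000 + 50 * i, "A", "G") for i in range(spec.n_loci)]
    verdicts_a: dict[tuple, str] = {}
    verdicts_b: dict[tuple, str] = {}
    classes: list[str] = (
        ["HLFP"] * spec.n_hlfp + ["LFP"] * spec.n_lfp + ["LTP"] * spec.n_ltp
    )
    n_disc = 0
    for locus, cls in zip(loci, classes):
        if cls == "HLFP":
            verdicts_a[locus], verdicts_b[locus] = FP, FP
        elif cls == "LTP":
            verdicts_a[locus], verdicts_b[locus] = TP, TP
        else:
            if n_disc % 2 == 0:
                verdicts_a[locus], verdicts_b[locus] = FP, TP
            else:
                verdicts_a[locus], verdicts_b[locus] = TP, FP
            n_disc += 1

    # flagged = HLFP + LFP loci, with carrier counts and corrected status
    samples = [f"s{i + 1:02d}" for i in range(spec.n_samples)]
    flagged_loci = loci[: spec.n_flagged]
    n_mid = spec.n_flagged - spec.n_singletons - spec.n_all_sample_variants
    carrier_counts = (
        [1] * spec.n_singletons
        + [spec.n_samples] * spec.n_all_sample_variants
        + [2 + (i % (spec.n_samples - 2)) for i in range(n_mid)]
    )
    mid_corrected = spec.n_corrected - spec.singleton_corrected - spec.all_sample_corrected
    corrected = (
        [True] * spec.singleton_corrected
        + [False] * (spec.n_singletons - spec.singleton_corrected)
        + [True] * spec.all_sample_corrected
        + [False] * (spec.n_all_sample_variants - spec.all_sample_corrected)
        + [True] * mid_corrected
        + [False] * (n_mid - mid_corrected)
    )
    flagged_calls: list[VariantCall] = []
    secondary_calls: list[VariantCall] = []
    for i, (locus, n_carriers, corr) in enumerate(zip(flagged_loci, carrier_counts, corrected)):
        chrom, pos, ref, alt = locus
        carriers = [samples[(i + j) % spec.n_samples] for j in range(n_carriers)]
        for s in carriers:
            call = VariantCall(s, GenomicLocus(chrom, pos), ref=ref, alt=alt)
            flagged_calls.append(call)
            if not corr:
                secondary_calls.append(call)
    return verdicts_a, verdicts_b, loci, flagged_calls, secondary_calls


def classification_truth_spec(spec: RaterFixtureSpec = PAPER_STRUCTURE) -> TruthSpec:
    """Mechanism counts whose classifier labels realise ``spec``'s HLFP
    error-type breakdown exactly.

    Multi-label loci are simplicity+cluster; simplicity splits into
    WHR-rich homopolymer windows vs copolymer windows below the WHR
    threshold; inversions split into MNV and paired del/ins forms (each
    pair is two loci).
    """
    spec.validate()
    simplicity_only = spec.simplicity - spec.multi_label
    n_delins_pairs = 2 if spec.base_inversion >= 4 else 0
    n_mnv = spec.base_inversion - 2 * n_delins_pairs
    return TruthSpec(
        n_common_true=0,
        n_ultrarare_true=spec.n_lfp + spec.n_ltp,
        n_homopolymer_indel=spec.whr_rich_simplicity,
        n_dinucleotide_snv=simplicity_only - spec.whr_rich_simplicity,
        n_simplicity_cluster=spec.multi_label,
        n_clustered_snv=spec.snv_cluster - spec.multi_label,
        n_end_of_read=spec.peripheral,
        n_inversion_mnv=n_mnv,
        n_inversion_delins_pairs=n_delins_pairs,
        n_low_coverage=0,
        n_noncds_decoy=0,
        n_norsid_decoy=0,
        n_sex_decoy=0,
    )


def make_classification_fixture(
    seed: int,
    spec: RaterFixtureSpec = PAPER_STRUCTURE,
    n_samples: int = 27,
    with_decoys: bool = True,
):
    """Seeded synthetic cohort whose injected mechanisms realise the
    packaged HLFP error-type breakdown, plus matching rater verdicts.

    Returns ``(cohort, verdicts_a, verdicts_b)``.  Error-mechanism loci
    are verdicted FP by both raters; the ultrarare-true loci split into
    discordant (LFP) and both-TP (LTP) groups in fixture order.  With
    ``with_decoys`` the cohort also carries common/non-CDS/no-rsID/sex
    decoy loci so the filter cascade is exercised end to end.
    """
    tspec = classification_truth_spec(spec)
    if with_decoys:
        tspec = replace(
            tspec, n_common_true=40, n_noncds_decoy=20, n_norsid_decoy=20, n_sex_decoy=6
        )
    cohort = simulate_cohort(tspec, n_samples=n_samples, seed=seed)

    verdicts_a: dict[tuple, str] = {}
    verdicts_b: dict[tuple, str] = {}
    n_true_seen = 0
    n_disc = 0
    for t in cohort.truth:
        if t.mechanism in _FILTERED_MECHANISMS:
            continue
        if t.mechanism == "TRUE_VARIANT":
            if n_true_seen < spec.n_lfp:
                if n_disc % 2 == 0:
                    verdicts_a[t.locus_key], verdicts_b[t.locus_key] = FP, TP
                else:
                    verdicts_a[t.locus_key], verdicts_b[t.locus_key] = TP, FP
                n_disc += 1
            else:
                verdicts_a[t.locus_key], verdicts_b[t.locus_key] = TP, TP
            n_true_seen += 1
        else:
            verdicts_a[t.locus_key], verdicts_b[t.locus_key] = FP, FP
    return cohort, verdicts_a, verdicts_b
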