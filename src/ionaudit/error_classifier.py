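"""The four alignment-level error patterns of semiconductor-sequencing
variant calls, and the classifier that assigns them.

* **Simplicity region** — the call sits in low-complexity sequence: a
  homopolymer-rich 19-bp window (WHR > 2.22) or a window flagged as
  AT/GC-rich or a dinucleotide repeat.  Flow-signal length errors and
  alignment biases concentrate in such contexts.
* **SNV cluster** — the call belongs to a group of ≥3 SNV calls of the
  same sample within a ≤50-bp span, the classic misalignment signature.
* **Peripheral sequence read** — the ALT-supporting reads place the
  variant within 5 bases of an aligned read end (where base quality
  degrades), for at least 80% of the supporting reads.
* **Base inversion** — 2–3 adjacent reference bases called with an ALT
  that is the reversal or a cyclic rotation of the REF (CG→GC, AGC→CAG),
  or the misaligned equivalent: a deletion and an insertion of the same
  base string anchored within 3 bp of each other.

The classifiers are independent: a variant may carry several labels, or
none (a candidate true positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

from .config import DEFAULT_CONFIG, AuditConfig
from .complexity import low_complexity_flags, whr, window_sequence
from .io_formats import AlignedRead, VariantCall
from .locus_filter import call_identity, normalize_alleles

__all__ = [
    "ERROR_TYPES",
    "ClassifiedVariant",
    "ClassificationContext",
    "supporting_reads",
    "classify_simplicity",
    "detect_snv_clusters",
    "classify_peripheral",
    "classify_base_inversion",
    "classify_variant",
    "classify_cohort",
]

SIMPLICITY = "SIMPLICITY"
SNV_CLUSTER = "SNV_CLUSTER"
PERIPHERAL = "PERIPHERAL"
BASE_INVERSION = "BASE_INVERSION"
ERROR_TYPES = (SIMPLICITY, SNV_CLUSTER, PERIPHERAL, BASE_INVERSION)


@dataclass(frozen=True)
class ClassifiedVariant:
    call: VariantCall
    error_types: frozenset
    evidence: Mapping[str, object]


@dataclass
class ClassificationContext:
    """Everything one sample's calls need for classification."""

    reference: Mapping[str, str]
    sample_calls: Sequence[VariantCall]
    reads: Sequence[AlignedRead]
    config: AuditConfig = field(default_factory=AuditConfig)


# ---------------------------------------------------------------------------
# read support


def _read_supports(call: VariantCall, read: AlignedRead) -> bool:
    pos = call.locus.pos
    vclass = call.variant_class
    if vclass in ("SNV", "MNV"):
        # every REF base must be aligned as a mismatch matching the ALT
        want = {pos + i: call.alt[i] for i in range(len(call.ref))}
        seen: dict[int, str] = {}
        for ev, ref_start, qpos in read.walk():
            if ev.op != "mismatch" or ref_start is None:
                continue
            for i in range(ev.length):
                p = ref_start + i
                if p in want:
                    seen[p] = read.sequence[qpos + i]
        return seen == want
    npos, nref, nalt = normalize_alleles(pos, call.ref, call.alt)
    if vclass == "DEL":
        del_start, del_len = npos + 1, len(nref) - 1
        for ev, ref_start, _ in read.walk():
            if ev.op == "delete" and ref_start == del_start and ev.length == del_len:
                return True
        return False
    # INS: inserted bases anchored right after npos
    inserted = nalt[1:]
    for ev, ref_start, _ in read.walk():
        if ev.op == "insert" and ref_start == npos and ev.bases == inserted:
            return True
    return False


def supporting_reads(call: VariantCall, reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Reads whose alignment expresses the call's ALT at its locus."""
    out = []
    for read in reads:
        if read.chrom != call.locus.chrom or not read.covers(call.locus.pos):
            continue
        if _read_supports(call, read):
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# simplicity region


def classify_simplicity(
    call: VariantCall,
    reference: Mapping[str, str],
    config: AuditConfig = DEFAULT_CONFIG,
) -> tuple[bool, dict]:
    """Low-complexity context: WHR-rich window or any qualitative flag."""
    seq = window_sequence(reference, call.locus, config.whr_window)
    res = whr(seq, config.whr_threshold)
    flags = low_complexity_flags(
        seq,
        at_rich_fraction=config.at_rich_fraction,
        gc_rich_fraction=config.gc_rich_fraction,
        dinucleotide_min_units=config.dinucleotide_min_units,
    )
    flagged = res.is_rich or any(flags.values())
    return flagged, {"whr": res.whr, "whr_rich": res.is_rich, **flags}


# ---------------------------------------------------------------------------
# SNV cluster


class ClusterFlag(NamedTuple):
    flagged: bool
    span: Optional[int] = None  # tightest qualifying span containing the call


def detect_snv_clusters(
    calls: Sequence[VariantCall],
    min_snvs: int = DEFAULT_CONFIG.cluster_min_snvs,
    span: int = DEFAULT_CONFIG.cluster_span,
) -> list[ClusterFlag]:
    """Flag each call of one sample that belongs to ≥``min_snvs`` SNV calls
    whose positional span (max − min + 1) is at most ``span``.

    Only SNV-class calls can be flagged or count toward a cluster.
    Returns flags parallel to the input order.
    """
    flags: list[ClusterFlag] = [ClusterFlag(False) for _ in calls]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, c in enumerate(calls):
        if c.variant_class == "SNV":
            by_chrom.setdefault(c.locus.chrom, []).append((c.locus.pos, idx))
    for entries in by_chrom.values():
        entries.sort()
        positions = [p for p, _ in entries]
        for i in range(len(entries) - min_snvs + 1):
            j = i + min_snvs - 1
            window_span = positions[j] - positions[i] + 1
            if window_span <= span:
                for _, idx in entries[i : j + 1]:
                    prev = flags[idx]
                    best = window_span if prev.span is None else min(prev.span, window_span)
                    flags[idx] = ClusterFlag(True, best)
    return flags


# ---------------------------------------------------------------------------
# peripheral sequence read


def classify_peripheral(
    call: VariantCall,
    reads: Sequence[AlignedRead],
    margin: int = DEFAULT_CONFIG.peripheral_margin,
    fraction: float = DEFAULT_CONFIG.peripheral_fraction,
) -> tuple[bool, dict]:
    """True iff ≥``fraction`` of ALT-supporting reads place the variant
    within ``margin`` bases (inclusive) of an aligned read end.

    Distance is measured on the aligned portion: offset 1 is the terminal
    aligned base, and soft clips do not shift the terminus.  With no
    supporting reads the verdict is False with the evidence saying so.
    """
    support = supporting_reads(call, reads)
    if not support:
        return False, {"reason": "no support", "n_support": 0, "peripheral_fraction": None}
    pos = call.locus.pos
    n_peripheral = 0
    for read in support:
        offset = min(pos - read.start + 1, read.end - pos + 1)
        if offset <= margin:
            n_peripheral += 1
    frac = n_peripheral / len(support)
    return frac >= fraction, {
        "n_support": len(support),
        "n_peripheral": n_peripheral,
        "peripheral_fraction": frac,
    }


# ---------------------------------------------------------------------------
# base inversion


class InversionFlag(NamedTuple):
    flagged: bool
    relation: Optional[str] = None  # 'reversal' | 'rotation' | 'del_ins_pair'
    partners: tuple = ()  # loci of the other calls in the flagged group


def _rotations(s: str) -> set[str]:
    return {s[i:] + s[:i] for i in range(1, len(s))}


def _inversion_relation(ref: str, alt: str) -> Optional[str]:
    if len(ref) != len(alt) or not (2 <= len(ref) <= 3) or ref == alt:
        return None
    if alt == ref[::-1]:
        return "reversal"
    if alt in _rotations(ref):
        return "rotation"
    return None


def classify_base_inversion(
    calls: Sequence[VariantCall],
    span: int = DEFAULT_CONFIG.inversion_span,
) -> list[InversionFlag]:
    """Flag inverted-call groups within one sample's calls.

    Rule (a): a group of adjacent SNV/MNV calls covering 2–3 contiguous
    reference bases whose concatenated ALT is the reversal or a cyclic
    rotation of the concatenated REF.  A single 2–3-bp MNV is such a group
    by itself.  Rule (b): a deletion and an insertion of the identical
    base string whose anchors lie within ``span`` bases — the misaligned
    representation of the same inversion.
    """
    flags: list[InversionFlag] = [InversionFlag(False) for _ in calls]

    def mark(indices: Sequence[int], relation: str) -> None:
        for idx in indices:
            if not flags[idx].flagged:
                others = tuple(
                    (calls[k].locus.chrom, calls[k].locus.pos) for k in indices if k != idx
                )
                flags[idx] = InversionFlag(True, relation, others)

    # rule (a): contiguous runs of substitution calls
    subs: dict[str, list[tuple[int, int]]] = {}
    for idx, c in enumerate(calls):
        if c.variant_class in ("SNV", "MNV"):
            subs.setdefault(c.locus.chrom, []).append((c.locus.pos, idx))
    for entries in subs.values():
        entries.sort()
        runs: list[list[int]] = []
        for pos, idx in entries:
            if runs and pos == calls[runs[-1][-1]].locus.pos + len(calls[runs[-1][-1]].ref):
                runs[-1].append(idx)
            else:
                runs.append([idx])
        for run in runs:
            for i in range(len(run)):
                ref = alt = ""
                for j in range(i, len(run)):
                    ref += calls[run[j]].ref
                    alt += calls[run[j]].alt
                    if len(ref) > 3:
                        break
                    relation = _inversion_relation(ref, alt)
                    if relation:
                        mark(run[i : j + 1], relation)

    # rule (b): paired deletion/insertion of the same string
    dels: list[tuple[int, int, str]] = []  # (anchor, idx, deleted)
    ins: list[tuple[int, int, str]] = []
    for idx, c in enumerate(calls):
        npos, nref, nalt = normalize_alleles(c.locus.pos, c.ref, c.alt)
        if c.variant_class == "DEL" and len(nalt) == 1:
            dels.append((npos, idx, nref[1:]))
        elif c.variant_class == "INS" and len(nref) == 1:
            ins.append((npos, idx, nalt[1:]))
    for dpos, didx, dstr in dels:
        for ipos, iidx, istr in ins:
            if (
                calls[didx].locus.chrom == calls[iidx].locus.chrom
                and dstr == istr
                and abs(dpos - ipos) <= span
            ):
                mark([didx, iidx], "del_ins_pair")
    return flags


# ---------------------------------------------------------------------------
# combined classification


def classify_variant(call: VariantCall, context: ClassificationContext) -> ClassifiedVariant:
    """Union of the four classifiers' verdicts for one call."""
    cfg = context.config
    types: set[str] = set()
    evidence: dict[str, object] = {}

    simp, simp_ev = classify_simplicity(call, context.reference, cfg)
    if simp:
        types.add(SIMPLICITY)
    evidence.update(simp_ev)

    sample_calls = list(context.sample_calls)
    try:
        my_idx = sample_calls.index(call)
    except ValueError:
        sample_calls.append(call)
        my_idx = len(sample_calls) - 1

    cluster = detect_snv_clusters(sample_calls, cfg.cluster_min_snvs, cfg.cluster_span)[my_idx]
    if cluster.flagged:
        types.add(SNV_CLUSTER)
    evidence["cluster_span"] = cluster.span

    peripheral, peri_ev = classify_peripheral(
        call, context.reads, cfg.peripheral_margin, cfg.peripheral_fraction
    )
    if peripheral:
        types.add(PERIPHERAL)
    evidence["peripheral_fraction"] = peri_ev.get("peripheral_fraction")
    evidence["n_support"] = peri_ev.get("n_support")

    inversion = classify_base_inversion(sample_calls, cfg.inversion_span)[my_idx]
    if inversion.flagged:
        types.add(BASE_INVERSION)
    evidence["inversion_relation"] = inversion.relation
    evidence["inversion_partners"] = inversion.partners

    return ClassifiedVariant(call=call, error_types=frozenset(types), evidence=evidence)


def classify_cohort(
    per_sample_calls: Mapping[str, Sequence[VariantCall]],
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    reference: Mapping[str, str],
    config: AuditConfig = DEFAULT_CONFIG,
    candidate_keys: Optional[set] = None,
) -> list[ClassifiedVariant]:
    """Classify every (candidate) call of every sample.

    Cluster and inversion flags are computed once per sample over its full
    call list (companion calls matter even when they are not themselves
    candidates); ``candidate_keys`` — allele-aware (chrom, pos, ref, alt)
    tuples — restricts which calls are emitted.
    """
    out: list[ClassifiedVariant] = []
    for sample, calls in per_sample_calls.items():
        calls = list(calls)
        reads = list(reads_by_sample.get(sample, ()))
        cluster_flags = detect_snv_clusters(calls, config.cluster_min_snvs, config.cluster_span)
        inversion_flags = classify_base_inversion(calls, config.inversion_span)
        reads_by_chrom: dict[str, list[AlignedRead]] = {}
        for r in reads:
            reads_by_chrom.setdefault(r.chrom, []).append(r)
        for idx, call in enumerate(calls):
            if candidate_keys is not None and call_identity(call) not in candidate_keys:
                continue
            types: set[str] = set()
            evidence: dict[str, object] = {}
            simp, simp_ev = classify_simplicity(call, reference, config)
            if simp:
                types.add(SIMPLICITY)
            evidence.update(simp_ev)
            if cluster_flags[idx].flagged:
                types.add(SNV_CLUSTER)
            evidence["cluster_span"] = cluster_flags[idx].span
            peripheral, peri_ev = classify_peripheral(
                call,
                reads_by_chrom.get(call.locus.chrom, ()),
                config.peripheral_margin,
                config.peripheral_fraction,
            )
            if peripheral:
                types.add(PERIPHERAL)
            evidence["peripheral_fraction"] = peri_ev.get("peripheral_fraction")
            evidence["n_support"] = peri_ev.get("n_support")
            if inversion_flags[idx].flagged:
                types.add(BASE_INVERSION)
            evidence["inversion_relation"] = inversion_flags[idx].relation
            evidence["inversion_partners"] = inversion_flags[idx].partners
            out.append(ClassifiedVariant(call=call, error_types=frozenset(types), evidence=evidence))
    return out
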