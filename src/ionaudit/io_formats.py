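"""Readers and writers for the formats the audit touches, with fixed
coordinate conventions.

Conventions used everywhere downstream:

* VCF positions and all internal analysis coordinates are **1-based**.
* BED intervals are **0-based half-open**; a BED line ``(c, s, e)`` covers
  1-based positions ``s+1 .. e``.
* Multi-allelic VCF records are split into one :class:`VariantCall` per
  alternate allele before any filtering, so set operations on calls are
  well-defined.
* Strand is a property of reads only (SAM FLAG bit 16); variant calls are
  strandless.

Parsing of VCF/SAM/BED is delegated to pysam and pyranges; this module only
converts to and from the audit's domain types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional

import pyranges
import pysam

__all__ = [
    "GenomicLocus",
    "Region",
    "VariantCall",
    "ReadEvent",
    "AlignedRead",
    "SiteTable",
    "VcfParseError",
    "SamParseError",
    "variant_class_of",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "read_sam",
    "write_sam",
    "read_site_table",
    "write_site_table",
    "read_fasta",
    "write_fasta",
]

_DNA = set("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF content; the message names the offending line."""


class SamParseError(ValueError):
    """Malformed SAM content (e.g. CIGAR/sequence length mismatch)."""


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A single 1-based reference position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True, order=True)
class Region:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def contains_pos(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` lies inside the interval."""
        return self.start + 1 <= pos <= self.end


def variant_class_of(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV, MNV, INS or DEL by length."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (one alternate allele).

    ``metrics`` carries the caller's per-call statistics under the keys
    ``AF`` (allele frequency), ``QUAL`` (call quality), ``DP`` (coverage)
    and ``SB`` (strand bias), any subset of which may be present.
    """

    sample_id: str
    locus: GenomicLocus
    ref: str
    alt: str
    rsid: Optional[str] = None
    metrics: Mapping[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.locus}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _DNA:
                raise ValueError(f"allele {allele!r} not over ACGT")

    @property
    def variant_class(self) -> str:
        return variant_class_of(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-aware identity used for set algebra and table lookups."""
        return (self.locus.chrom, self.locus.pos, self.ref, self.alt)

    @property
    def pos_key(self) -> tuple[str, int]:
        return (self.locus.chrom, self.locus.pos)


class ReadEvent(NamedTuple):
    """One alignment event of a read.

    ``op`` is one of ``match``, ``mismatch``, ``insert``, ``delete``,
    ``clip`` (soft clip).  ``bases`` holds the read bases for mismatch /
    insert / clip events and is empty for match / delete.
    """

    op: str
    length: int
    bases: str = ""


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read: start, strand, and its ordered event list.

    The reference footprint is ``start .. start + sum(match, mismatch,
    delete lengths) - 1``.  Soft clips are kept in the event list (they
    consume read bases) but never consume reference; hard clips are
    dropped entirely, consistent with their absence from SEQ.
    """

    read_id: str
    chrom: str
    start: int  # 1-based leftmost aligned reference position
    strand: str  # '+' or '-'
    events: tuple[ReadEvent, ...]
    sequence: str

    def __post_init__(self) -> None:
        read_len = sum(
            e.length for e in self.events if e.op in ("match", "mismatch", "insert", "clip")
        )
        if read_len != len(self.sequence):
            raise SamParseError(
                f"read {self.read_id}: events consume {read_len} bases but "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def reference_span(self) -> int:
        return sum(e.length for e in self.events if e.op in ("match", "mismatch", "delete"))

    @property
    def end(self) -> int:
        """1-based rightmost aligned reference position (inclusive)."""
        return self.start + self.reference_span - 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def walk(self):
        """Yield ``(event, ref_start, read_start)`` over the event list.

        ``ref_start`` is the 1-based reference position the event begins
        at (for insertions: the anchor base the insertion follows; for
        clips: None).  ``read_start`` is the 0-based offset into
        ``sequence`` of the event's first read base.
        """
        ref = self.start
        qpos = 0
        for ev in self.events:
            if ev.op == "clip":
                yield ev, None, qpos
                qpos += ev.length
            elif ev.op == "insert":
                yield ev, ref - 1, qpos
                qpos += ev.length
            elif ev.op == "delete":
                yield ev, ref, qpos
                ref += ev.length
            else:  # match / mismatch
                yield ev, ref, qpos
                ref += ev.length
                qpos += ev.length


# ---------------------------------------------------------------------------
# VCF


def _validate_vcf_text(path: Path) -> None:
    saw_chrom_header = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if raw.startswith("##"):
            continue
        if raw.startswith("#CHROM"):
            saw_chrom_header = True
            continue
        if not raw.strip():
            continue
        if not saw_chrom_header:
            raise VcfParseError(f"{path}:{lineno}: data before #CHROM header line")
        fields = raw.split("\t")
        if len(fields) < 8:
            raise VcfParseError(
                f"{path}:{lineno}: expected >= 8 tab-separated fields, got {len(fields)}"
            )
        try:
            int(fields[1])
        except ValueError:
            raise VcfParseError(f"{path}:{lineno}: POS {fields[1]!r} is not an integer") from None
    if not saw_chrom_header:
        raise VcfParseError(f"{path}: missing #CHROM header line")


def _scalar(value, allele_index: int):
    if isinstance(value, tuple):
        return value[allele_index] if allele_index < len(value) else value[0]
    return value


def read_vcf(path: str | Path, sample_id: Optional[str] = None) -> list[VariantCall]:
    """Read a VCF into per-sample, per-allele :class:`VariantCall` objects.

    Multi-allelic records are split; REF/ALT are uppercased.  If the file
    has genotype columns, one call is emitted per sample whose genotype
    carries the allele; otherwise calls get ``sample_id`` (default: the
    file stem).
    """
    path = Path(path)
    _validate_vcf_text(path)
    default_sample = sample_id if sample_id is not None else path.stem
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_samples = len(vcf.header.samples) > 0
        for rec in vcf:
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts):
                metrics: dict[str, float] = {}
                if "AF" in rec.info:
                    metrics["AF"] = float(_scalar(rec.info["AF"], ai))
                if rec.qual is not None:
                    metrics["QUAL"] = float(rec.qual)
                if "DP" in rec.info:
                    metrics["DP"] = float(_scalar(rec.info["DP"], ai))
                if "SB" in rec.info:
                    metrics["SB"] = float(_scalar(rec.info["SB"], ai))
                base = dict(
                    locus=GenomicLocus(rec.chrom, rec.pos),
                    ref=rec.ref.upper(),
                    alt=alt.upper(),
                    rsid=rec.id,
                    metrics=metrics,
                )
                if has_samples:
                    for sample in rec.samples.values():
                        gt = sample.get("GT") or ()
                        if (ai + 1) in gt:
                            calls.append(VariantCall(sample_id=sample.name, **base))
                else:
                    calls.append(VariantCall(sample_id=default_sample, **base))
    return calls


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write calls as a single-column (site-only) VCF v4.2 file.

    Caller metrics go to INFO keys AF/DP/SB and the QUAL column.  Input
    must already be sorted by (chrom, pos).
    """
    calls = list(calls)
    order = [(c.locus.chrom, c.locus.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by (chrom, pos) before writing")

    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                                   ("Description", "Allele frequency")])
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Read depth")])
    header.add_meta("INFO", items=[("ID", "SB"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Strand bias")])
    lengths: dict[str, int] = dict(contig_lengths or {})
    for c in calls:
        need = c.locus.pos + len(c.ref) + 1000
        if lengths.get(c.locus.chrom, 0) < need:
            lengths[c.locus.chrom] = max(lengths.get(c.locus.chrom, 0), need)
    for chrom, length in lengths.items():
        header.contigs.add(chrom, length=length)

    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.locus.chrom,
                start=c.locus.pos - 1,
                alleles=(c.ref, c.alt),
                id=c.rsid,
            )
            if "QUAL" in c.metrics:
                rec.qual = float(c.metrics["QUAL"])
            if "AF" in c.metrics:
                rec.info["AF"] = float(c.metrics["AF"])
            if "DP" in c.metrics:
                rec.info["DP"] = int(c.metrics["DP"])
            if "SB" in c.metrics:
                rec.info["SB"] = float(c.metrics["SB"])
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, merge: bool = False) -> list[Region]:
    """Read a BED3+ file into 0-based half-open Regions.

    Overlapping lines are preserved as-is unless ``merge`` is set, in which
    case overlapping/bookended intervals are unioned per chromosome.
    """
    gr = pyranges.read_bed(str(path))
    if merge and len(gr) > 0:
        gr = gr.merge()
    regions = [
        Region(str(row.Chromosome), int(row.Start), int(row.End))
        for row in gr.df.itertuples(index=False)
    ]
    return sorted(regions)


# ---------------------------------------------------------------------------
# SAM

_CIGAR_TO_OP = {0: "match", 1: "insert", 2: "delete", 4: "clip", 7: "match", 8: "mismatch"}
_OP_TO_CIGAR = {"match": 7, "mismatch": 8, "insert": 1, "delete": 2, "clip": 4}


def _events_from_segment(
    seg: pysam.AlignedSegment, reference: Optional[Mapping[str, str]]
) -> tuple[ReadEvent, ...]:
    seq = seg.query_sequence or ""
    events: list[ReadEvent] = []
    qpos = 0
    rpos = seg.reference_start  # 0-based
    for code, length in seg.cigartuples or ():
        if code == 5:  # hard clip: consumes nothing present in SEQ
            continue
        if code not in _CIGAR_TO_OP and code != 0:
            raise SamParseError(f"read {seg.query_name}: unsupported CIGAR op code {code}")
        if code == 0 and reference is not None:
            # plain M: resolve to match/mismatch runs against the reference
            ref_seq = reference[seg.reference_name][rpos : rpos + length].upper()
            read_seq = seq[qpos : qpos + length].upper()
            i = 0
            while i < length:
                j = i
                is_mm = read_seq[j] != ref_seq[j]
                while j < length and (read_seq[j] != ref_seq[j]) == is_mm:
                    j += 1
                if is_mm:
                    events.append(ReadEvent("mismatch", j - i, read_seq[i:j]))
                else:
                    events.append(ReadEvent("match", j - i))
                i = j
            qpos += length
            rpos += length
            continue
        op = _CIGAR_TO_OP[code]
        if op in ("match", "mismatch", "insert", "clip"):
            bases = seq[qpos : qpos + length].upper() if op != "match" else ""
            events.append(ReadEvent(op, length, bases))
            qpos += length
        else:  # delete
            events.append(ReadEvent("delete", length))
        if op in ("match", "mismatch", "delete"):
            rpos += length
    if qpos != len(seq):
        raise SamParseError(
            f"read {seg.query_name}: CIGAR consumes {qpos} bases, sequence has {len(seq)}"
        )
    return tuple(events)


def read_sam(
    path: str | Path, reference: Optional[Mapping[str, str]] = None
) -> list[AlignedRead]:
    """Read a text SAM file into :class:`AlignedRead` objects.

    Reads aligned with plain ``M`` CIGAR ops are split into match/mismatch
    runs when ``reference`` (a chrom → sequence mapping) is supplied;
    without it, ``M`` is taken as match.  Unmapped reads are skipped.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    start=seg.reference_start + 1,
                    strand="-" if seg.is_reverse else "+",
                    events=_events_from_segment(seg, reference),
                    sequence=(seg.query_sequence or "").upper(),
                )
            )
    return reads


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write reads as coordinate-sorted text SAM v1.6 with =/X CIGAR ops."""
    reads = sorted(reads, key=lambda r: (r.chrom, r.start, r.read_id))
    lengths: dict[str, int] = dict(contig_lengths or {})
    for r in reads:
        if lengths.get(r.chrom, 0) < r.end:
            lengths[r.chrom] = r.end + 1
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(length)} for chrom, length in sorted(lengths.items())],
    }
    path = Path(path)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = tid[r.chrom]
            seg.reference_start = r.start - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_TO_CIGAR[e.op], e.length) for e in r.events]
            seg.query_sequence = r.sequence
            out.write(seg)
    return path


# ---------------------------------------------------------------------------
# Site tables (dbSNP / population catalogue stand-ins)


class SiteTable:
    """Hashable membership structure over (chrom, pos, ref, alt) rows.

    Supports allele-aware lookup (the default downstream) and a
    position-only mode mirroring the locus-identity flag.
    """

    def __init__(self, rows: Iterable[tuple[str, int, str, str, Optional[float]]]):
        self._af: dict[tuple[str, int, str, str], Optional[float]] = {}
        self._positions: set[tuple[str, int]] = set()
        for chrom, pos, ref, alt, af in rows:
            key = (chrom, int(pos), ref.upper(), alt.upper())
            if key in self._af and self._af[key] != af:
                raise ValueError(f"conflicting duplicate rows for {key}")
            self._af[key] = af
            self._positions.add((chrom, int(pos)))

    def __len__(self) -> int:
        return len(self._af)

    def __contains__(self, key: tuple) -> bool:
        if len(key) == 2:
            return key in self._positions
        return tuple(key) in self._af

    def contains_call(self, call: VariantCall, allele_aware: bool = True) -> bool:
        if allele_aware:
            return call.key in self._af
        return call.pos_key in self._positions

    def frequency(self, key: tuple[str, int, str, str]) -> Optional[float]:
        return self._af.get(key)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return set(self._af)


def read_site_table(path: str | Path) -> SiteTable:
    """Read a TSV with header ``chrom pos ref alt [af]`` into a SiteTable."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: site table needs columns {sorted(required)}")
    has_af = "af" in df.columns
    rows = (
        (r.chrom, int(r.pos), r.ref, r.alt, float(r.af) if has_af else None)
        for r in df.itertuples(index=False)
    )
    return SiteTable(rows)


def write_site_table(
    rows: Iterable[tuple[str, int, str, str, Optional[float]]], path: str | Path
) -> Path:
    import pandas as pd

    rows = list(rows)
    with_af = any(r[4] is not None for r in rows)
    cols = ["chrom", "pos", "ref", "alt"] + (["af"] if with_af else [])
    df = pd.DataFrame(
        [r[: 4 + (1 if with_af else 0)] for r in rows], columns=cols
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
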