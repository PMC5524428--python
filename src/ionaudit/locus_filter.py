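"""Cascade that reduces raw multi-sample calls to ultrarare candidate loci.

An *ultrarare* variant here is one with a dbSNP rsID that is absent from
both large population catalogues (1000 Genomes phase 3 and ExAC): reported
at least once, yet never seen in well-curated cohorts — exactly the calls
most likely to be platform artifacts.

The cascade runs in a fixed order, each step recording a
:class:`FilterTrace` so the per-step exclusion counts can be reconstructed:

1. keep calls inside CDS target regions,
2. keep calls with a known rsID (dbSNP membership),
3. drop calls present in 1000 Genomes phase 3,
4. drop calls present in ExAC,
5. drop calls on sex chromosomes.

Locus identity for all set operations is allele-aware (chrom, pos, ref,
alt) by default; a position-only mode is available behind a flag.  Indel
allele pairs are normalised (trim common suffix, then common prefix,
keeping a 1-base anchor) before table lookups so that left-aligned and
anchored representations match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import Region, SiteTable, VariantCall

__all__ = [
    "FilterTrace",
    "LocusKey",
    "normalize_alleles",
    "call_identity",
    "intersect_cds",
    "require_known_rsid",
    "exclude_population_variants",
    "exclude_sex_chromosomes",
    "select_error_prone_loci",
]

LocusKey = tuple
_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

STEP_ORDER = ("cds", "rsid", "t1gp", "exac", "sex_chromosomes")


@dataclass
class FilterTrace:
    """Bookkeeping for one cascade step over distinct loci."""

    step: str
    loci_in: int
    loci_out: int
    removed: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.loci_out != self.loci_in - len(self.removed):
            raise ValueError(
                f"{self.step}: loci_out {self.loci_out} != loci_in {self.loci_in} "
                f"- removed {len(self.removed)}"
            )


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Canonicalise an allele pair: trim the common suffix, then the common
    prefix, always keeping at least one base on each side.

    The position advances by the number of prefix bases trimmed, so
    anchored and left-shifted indel representations collapse to one key.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def call_identity(call: VariantCall, allele_aware: bool = True) -> LocusKey:
    """Set-operation identity of a call (normalised alleles by default)."""
    if not allele_aware:
        return call.pos_key
    pos, ref, alt = normalize_alleles(call.locus.pos, call.ref, call.alt)
    return (call.locus.chrom, pos, ref, alt)


def _distinct_loci(calls: Iterable[VariantCall], allele_aware: bool) -> set:
    return {call_identity(c, allele_aware) for c in calls}


def _trace(
    step: str,
    calls_in: Sequence[VariantCall],
    calls_out: Sequence[VariantCall],
    allele_aware: bool,
) -> FilterTrace:
    loci_in = _distinct_loci(calls_in, allele_aware)
    loci_out = _distinct_loci(calls_out, allele_aware)
    return FilterTrace(
        step=step,
        loci_in=len(loci_in),
        loci_out=len(loci_out),
        removed=loci_in - loci_out,
    )


def intersect_cds(
    calls: Sequence[VariantCall],
    cds_regions: Sequence[Region],
    traces: Optional[list[FilterTrace]] = None,
    allele_aware: bool = True,
) -> list[VariantCall]:
    """Keep calls whose position lies inside a CDS region.

    An empty region set is an error: it almost always means a
    misconfigured BED path rather than a genuinely empty intersection.
    """
    if not cds_regions:
        raise ValueError("CDS region set is empty; refusing to drop every call")
    by_chrom: dict[str, list[Region]] = {}
    for r in cds_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    survivors = [
        c
        for c in calls
        if any(r.contains_pos(c.locus.pos) for r in by_chrom.get(c.locus.chrom, ()))
    ]
    if traces is not None:
        traces.append(_trace("cds", calls, survivors, allele_aware))
    return survivors


def require_known_rsid(
    calls: Sequence[VariantCall],
    dbsnp_table: SiteTable,
    traces: Optional[list[FilterTrace]] = None,
    allele_aware: bool = True,
) -> list[VariantCall]:
    """Keep calls whose (normalised) locus/alleles appear in the dbSNP
    stand-in table."""
    survivors = [c for c in calls if _in_table(c, dbsnp_table, allele_aware)]
    if traces is not None:
        traces.append(_trace("rsid", calls, survivors, allele_aware))
    return survivors


def _in_table(call: VariantCall, table: SiteTable, allele_aware: bool) -> bool:
    if not allele_aware:
        return call.pos_key in table
    return call_identity(call, True) in table


def exclude_population_variants(
    calls: Sequence[VariantCall],
    t1gp_table: SiteTable,
    exac_table: SiteTable,
    traces: Optional[list[FilterTrace]] = None,
    allele_aware: bool = True,
) -> list[VariantCall]:
    """Remove calls found in either population catalogue, tracing the
    1000 Genomes step before the ExAC step."""
    after_t1gp = [c for c in calls if not _in_table(c, t1gp_table, allele_aware)]
    if traces is not None:
        traces.append(_trace("t1gp", calls, after_t1gp, allele_aware))
    after_exac = [c for c in after_t1gp if not _in_table(c, exac_table, allele_aware)]
    if traces is not None:
        traces.append(_trace("exac", after_t1gp, after_exac, allele_aware))
    return after_exac


def exclude_sex_chromosomes(
    calls: Sequence[VariantCall],
    traces: Optional[list[FilterTrace]] = None,
    allele_aware: bool = True,
) -> list[VariantCall]:
    survivors = [c for c in calls if c.locus.chrom not in _SEX_CHROMS]
    if traces is not None:
        traces.append(_trace("sex_chromosomes", calls, survivors, allele_aware))
    return survivors


def select_error_prone_loci(
    per_sample_calls: dict[str, Sequence[VariantCall]],
    cds_regions: Sequence[Region],
    dbsnp: SiteTable,
    t1gp: SiteTable,
    exac: SiteTable,
    allele_aware: bool = True,
) -> tuple[set, list[FilterTrace], dict[str, list[VariantCall]]]:
    """Run the full cascade over the pooled cohort.

    Returns the surviving distinct loci, the per-step traces (computed on
    distinct loci pooled across samples), and the surviving calls per
    sample, so per-sample statistics and carrier counts remain available
    downstream.
    """
    if not per_sample_calls:
        raise ValueError("need at least one sample")
    pooled: list[VariantCall] = [c for calls in per_sample_calls.values() for c in calls]
    traces: list[FilterTrace] = []
    pooled = intersect_cds(pooled, cds_regions, traces, allele_aware)
    pooled = require_known_rsid(pooled, dbsnp, traces, allele_aware)
    pooled = exclude_population_variants(pooled, t1gp, exac, traces, allele_aware)
    pooled = exclude_sex_chromosomes(pooled, traces, allele_aware)
    survivors = _distinct_loci(pooled, allele_aware)
    per_sample_out: dict[str, list[VariantCall]] = {
        sample: [c for c in calls if call_identity(c, allele_aware) in survivors]
        for sample, calls in per_sample_calls.items()
    }
    return survivors, traces, per_sample_out
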