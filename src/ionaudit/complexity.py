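"""Sequence-complexity measures around a variant position.

The central statistic is the weighted homopolymer rate (WHR) of a window:

    WHR = (sum_i n_i^2) / N

where the window decomposes into N maximal single-base runs of lengths
n_1..n_N.  A window of all-distinct neighbours has WHR = 1; a single run of
length L has WHR = L^2.  Windows with WHR > 2.22 are treated as
homopolymer-rich.  The default window is 19 bp: 9 bp either side of the
variant's anchor position, truncated (never padded) at contig ends.

Auxiliary qualitative low-complexity flags (AT-rich, GC-rich, dinucleotide
repeat) catch copolymer and skewed-composition contexts that a pure
homopolymer statistic misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Mapping

from .config import DEFAULT_CONFIG
from .io_formats import GenomicLocus

__all__ = [
    "WhrResult",
    "homopolymer_runs",
    "whr",
    "whr_window",
    "low_complexity_flags",
    "window_sequence",
    "whr_window_sweep",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class WhrResult:
    window_sequence: str
    runs: tuple[int, ...]
    n_runs: int
    whr: float
    is_rich: bool


def homopolymer_runs(seq: str) -> list[int]:
    """Maximal-run decomposition of ``seq``; order preserved.

    'N' bases form their own (possibly multi-base broken into length-1)
    runs: each N counts as a run of length 1, keeping sum(runs) == len(seq)
    without crediting ambiguous sequence as homopolymer.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if set(seq) - _ALPHABET:
        raise ValueError(f"sequence contains non-ACGTN characters: {set(seq) - _ALPHABET}")
    runs: list[int] = []
    for base, grp in groupby(seq):
        n = sum(1 for _ in grp)
        if base == "N":
            runs.extend([1] * n)
        else:
            runs.append(n)
    return runs


def whr(seq: str, threshold: float = DEFAULT_CONFIG.whr_threshold) -> WhrResult:
    """Weighted homopolymer rate of ``seq``; rich iff strictly > threshold."""
    runs = homopolymer_runs(seq)
    value = sum(n * n for n in runs) / len(runs)
    return WhrResult(
        window_sequence=seq.upper(),
        runs=tuple(runs),
        n_runs=len(runs),
        whr=value,
        is_rich=value > threshold,
    )


def window_sequence(
    reference: Mapping[str, str], locus: GenomicLocus, window: int = DEFAULT_CONFIG.whr_window
) -> str:
    """Extract the window of ``window`` bp centred on ``locus`` (1-based),
    truncated at contig ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    if locus.chrom not in reference:
        raise KeyError(f"chromosome {locus.chrom!r} not in reference")
    contig = reference[locus.chrom]
    if not (1 <= locus.pos <= len(contig)):
        raise ValueError(f"position {locus.pos} outside contig {locus.chrom} (len {len(contig)})")
    half = window // 2
    lo = max(1, locus.pos - half)
    hi = min(len(contig), locus.pos + half)
    return contig[lo - 1 : hi].upper()


def whr_window(
    reference: Mapping[str, str],
    locus: GenomicLocus,
    window: int = DEFAULT_CONFIG.whr_window,
    threshold: float = DEFAULT_CONFIG.whr_threshold,
) -> WhrResult:
    """WHR of the window centred at the variant anchor position.

    For SNVs the anchor is the variant position itself; for indels it is
    the VCF anchor base.
    """
    return whr(window_sequence(reference, locus, window), threshold)


def low_complexity_flags(
    seq: str,
    at_rich_fraction: float = DEFAULT_CONFIG.at_rich_fraction,
    gc_rich_fraction: float = DEFAULT_CONFIG.gc_rich_fraction,
    dinucleotide_min_units: int = DEFAULT_CONFIG.dinucleotide_min_units,
) -> dict[str, bool]:
    """Qualitative low-complexity flags of a window.

    at_rich / gc_rich: base-composition fraction at or above the cutoff
    (default 0.8).  dinucleotide_repeat: some two-base unit XY with X != Y
    repeated at least ``dinucleotide_min_units`` times consecutively.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    at = sum(seq.count(b) for b in "AT") / n
    gc = sum(seq.count(b) for b in "GC") / n
    dinuc = False
    need = 2 * dinucleotide_min_units
    for i in range(n - need + 1):
        unit = seq[i : i + 2]
        if unit[0] == unit[1] or set(unit) - set("ACGT"):
            continue
        if seq[i : i + need] == unit * dinucleotide_min_units:
            dinuc = True
            break
    return {
        "at_rich": at >= at_rich_fraction,
        "gc_rich": gc >= gc_rich_fraction,
        "dinucleotide_repeat": dinuc,
    }


def whr_window_sweep(
    reference: Mapping[str, str],
    loci: list[GenomicLocus],
    window_sizes: range | list[int] = range(3, 252, 2),
    threshold: float = DEFAULT_CONFIG.whr_threshold,
) -> "pandas.DataFrame":  # noqa: F821
    """Utility sweep of WHR across window sizes for a set of loci.

    Returns one row per (locus, window) with the WHR value and rich flag.
    The packaged default window of 19 bp is taken as given; this helper
    lets users rerun the sweep on their own data.
    """
    import pandas as pd

    rows = []
    for locus in loci:
        for w in window_sizes:
            res = whr_window(reference, locus, window=w, threshold=threshold)
            rows.append((locus.chrom, locus.pos, w, res.whr, res.is_rich))
    return pd.DataFrame(rows, columns=["chrom", "pos", "window", "whr", "is_rich"])
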