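"""Two-rater curation: merge FP/TP verdicts into consensus classes and
quantify inter-rater agreement.

Each candidate locus is inspected independently by two raters, each issuing
a binary verdict: FP (false positive) or TP (true positive).  The merge is:

* both say FP  → HLFP (highly likely false positive)
* raters split → LFP  (likely false positive)
* both say TP  → LTP  (likely true positive)

The error-type category a rater may have had in mind does not enter the
consensus; verdicts are strictly binary.  Agreement is summarised with
Cohen's kappa, κ = (p_o − p_e) / (1 − p_e), where p_o is observed agreement
and p_e the chance agreement from the marginal verdict rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "FP",
    "TP",
    "RaterVerdict",
    "ConsensusClass",
    "consensus_class",
    "merge_verdicts",
    "cohens_kappa",
    "consensus_summary",
]

FP = "FP"
TP = "TP"
_CLASSES = ("HLFP", "LFP", "LTP")


@dataclass(frozen=True)
class RaterVerdict:
    rater_id: str
    locus: tuple
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in (FP, TP):
            raise ValueError(f"verdict must be FP or TP, got {self.verdict!r}")


@dataclass(frozen=True)
class ConsensusClass:
    locus: tuple
    consensus: str

    def __post_init__(self) -> None:
        if self.consensus not in _CLASSES:
            raise ValueError(f"consensus must be one of {_CLASSES}")


def consensus_class(verdict_a: str, verdict_b: str) -> str:
    """Merge two binary verdicts for one locus into HLFP/LFP/LTP."""
    for v in (verdict_a, verdict_b):
        if v not in (FP, TP):
            raise ValueError(f"verdict must be FP or TP, got {v!r}")
    if verdict_a == verdict_b:
        return "HLFP" if verdict_a == FP else "LTP"
    return "LFP"


def merge_verdicts(
    verdicts_a: Mapping[tuple, str], verdicts_b: Mapping[tuple, str]
) -> dict[tuple, str]:
    """Per-locus consensus over two complete verdict tables.

    Both raters must have verdicted exactly the same locus set; a missing
    verdict on either side is an error rather than a silent skip.
    """
    if set(verdicts_a) != set(verdicts_b):
        only_a = set(verdicts_a) - set(verdicts_b)
        only_b = set(verdicts_b) - set(verdicts_a)
        raise ValueError(
            f"verdict tables cover different loci ({len(only_a)} only in A, "
            f"{len(only_b)} only in B)"
        )
    return {locus: consensus_class(verdicts_a[locus], verdicts_b[locus]) for locus in verdicts_a}


def cohens_kappa(
    verdicts_a: Mapping[tuple, str] | Sequence[str],
    verdicts_b: Mapping[tuple, str] | Sequence[str],
) -> float:
    """Cohen's kappa for two binary verdict vectors over the same loci.

    Degenerate case: if both raters are constant and identical, chance
    agreement p_e = 1; κ is defined as 1 when observed agreement is also
    perfect (it necessarily is), mirroring the limit of the formula.
    """
    if isinstance(verdicts_a, Mapping):
        if not isinstance(verdicts_b, Mapping) or set(verdicts_a) != set(verdicts_b):
            raise ValueError("verdict tables must cover the same loci")
        loci = sorted(verdicts_a)
        a = [verdicts_a[l] for l in loci]
        b = [verdicts_b[l] for l in loci]
    else:
        a, b = list(verdicts_a), list(verdicts_b)
        if len(a) != len(b):
            raise ValueError("verdict vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("no verdicts")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa_fp = a.count(FP) / n
    pb_fp = b.count(FP) / n
    p_e = pa_fp * pb_fp + (1 - pa_fp) * (1 - pb_fp)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("chance agreement is 1 but observed agreement is not")
    return (p_o - p_e) / (1 - p_e)


def consensus_summary(consensus: Mapping[tuple, str]) -> dict[str, dict[str, float]]:
    """Counts and percentages of the HLFP/LFP/LTP partition.

    Returns ``{"counts": {...}, "percent": {...}, "total": n}`` with
    percentages of the verdicted total (summing to 100 up to rounding).
    """
    counts = {c: 0 for c in _CLASSES}
    for cls in consensus.values():
        counts[cls] += 1
    total = len(consensus)
    percent = {c: (100.0 * counts[c] / total if total else 0.0) for c in _CLASSES}
    return {"counts": counts, "percent": percent, "total": total}
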