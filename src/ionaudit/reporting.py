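"""Cohort-level summaries: concordance against a secondary caller,
kit-group comparisons, depth comparisons, and error-type proportions.

The concordance question: of the variants flagged as (highly) likely false
positives by the audit, how many does a local de-novo-assembly caller
refuse to reproduce?  A flagged variant counts as *corrected* when the
secondary call set lacks it in **every** sample that carried it (a
per-sample-call mode is exposed for the looser reading).

Kit comparisons contrast the two sequencing chemistries (S200V3 vs HiQ)
with per-sample counts and a two-sided Student's t-test (equal variance by
default, Welch behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .curation import consensus_summary
from .error_classifier import ERROR_TYPES, ClassifiedVariant
from .io_formats import VariantCall
from .locus_filter import call_identity

__all__ = [
    "ConcordanceTable",
    "correction_concordance",
    "singleton_correction",
    "kit_comparison",
    "depth_comparison",
    "proportions_report",
    "low_coverage_report",
]


@dataclass
class ConcordanceTable:
    """Per carrier-count bin: how many flagged variants the primary caller
    produced and how many of those the secondary caller reproduced."""

    bins: dict[int, dict[str, int]] = field(default_factory=dict)
    corrected: int = 0
    retained: int = 0

    @property
    def total(self) -> int:
        return self.corrected + self.retained

    @property
    def corrected_percent(self) -> float:
        return 100.0 * self.corrected / self.total if self.total else 0.0


def _carriers(calls: Sequence[VariantCall], allele_aware: bool = True) -> dict:
    out: dict[tuple, set[str]] = {}
    for c in calls:
        out.setdefault(call_identity(c, allele_aware), set()).add(c.sample_id)
    return out


def correction_concordance(
    flagged_calls: Sequence[VariantCall],
    secondary_calls: Sequence[VariantCall],
    allele_aware: bool = True,
    per_sample: bool = False,
) -> ConcordanceTable:
    """Tabulate flagged variants by carrier count, splitting corrected vs
    retained against the secondary call set.

    Default mode counts variants (loci): corrected iff absent from the
    secondary set for every carrying sample.  ``per_sample=True`` counts
    sample-level calls instead.
    """
    flagged = _carriers(flagged_calls, allele_aware)
    secondary = _carriers(secondary_calls, allele_aware)
    table = ConcordanceTable()
    for key, samples in flagged.items():
        sec_samples = secondary.get(key, set())
        n = len(samples)
        entry = table.bins.setdefault(n, {"primary": 0, "secondary": 0})
        if per_sample:
            entry["primary"] += n
            reproduced = len(samples & sec_samples)
            entry["secondary"] += reproduced
            table.corrected += n - reproduced
            table.retained += reproduced
        else:
            entry["primary"] += 1
            reproduced = bool(samples & sec_samples)
            entry["secondary"] += int(reproduced)
            if reproduced:
                table.retained += 1
            else:
                table.corrected += 1
    return table


def singleton_correction(
    flagged_calls: Sequence[VariantCall],
    secondary_calls: Sequence[VariantCall],
    allele_aware: bool = True,
) -> dict[str, float]:
    """Among flagged variants carried by exactly one sample, count those
    the secondary caller does not reproduce."""
    flagged = _carriers(flagged_calls, allele_aware)
    secondary = _carriers(secondary_calls, allele_aware)
    singletons = {k: s for k, s in flagged.items() if len(s) == 1}
    corrected = sum(1 for k, s in singletons.items() if not (s & secondary.get(k, set())))
    n = len(singletons)
    return {
        "n_singletons": n,
        "corrected": corrected,
        "corrected_percent": 100.0 * corrected / n if n else 0.0,
    }


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def kit_comparison(
    sample_values: Mapping[str, Mapping[str, Sequence[float]]],
    welch: bool = False,
) -> "pandas.DataFrame":  # noqa: F821
    """Per-stratum kit contrast: group mean ± SD and a two-sided t-test.

    ``sample_values`` maps stratum (e.g. 'SNV', 'INDEL', or an error type)
    → kit name → per-sample values.  Each stratum needs exactly two kit
    groups with ≥2 samples each.
    """
    import pandas as pd

    rows = []
    for stratum, groups in sample_values.items():
        if len(groups) != 2:
            raise ValueError(f"stratum {stratum!r}: need exactly two kit groups")
        (kit_a, va), (kit_b, vb) = sorted(groups.items())
        va, vb = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"stratum {stratum!r}: each kit group needs >= 2 samples")
        t, p = _two_sample_t(va, vb, welch)
        rows.append(
            {
                "stratum": stratum,
                "kit_a": kit_a,
                "kit_b": kit_b,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1),
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def depth_comparison(
    depth_by_class: Mapping[str, Mapping[str, Sequence[float]]],
    welch: bool = False,
) -> dict:
    """Coverage-depth contrast across variant classes and kits.

    ``depth_by_class`` maps class (e.g. 'HLFP', 'error_prone',
    'non_error_prone') → kit → per-locus depths.  Returns per-(class, kit)
    mean/SD/median plus two-sided tests: between kits within each class,
    and between classes pooled over kits.
    """
    summary: dict[str, dict[str, dict[str, float]]] = {}
    for cls, kits in depth_by_class.items():
        if not kits or any(len(v) == 0 for v in kits.values()):
            raise ValueError(f"class {cls!r}: empty depth group")
        summary[cls] = {}
        for kit, vals in kits.items():
            arr = np.asarray(vals, dtype=float)
            summary[cls][kit] = {
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "median": float(np.median(arr)),
            }
    kit_tests: dict[str, dict[str, float]] = {}
    for cls, kits in depth_by_class.items():
        if len(kits) == 2:
            (ka, va), (kb, vb) = sorted(kits.items())
            if len(va) >= 2 and len(vb) >= 2:
                t, p = _two_sample_t(np.asarray(va, float), np.asarray(vb, float), welch)
                kit_tests[cls] = {"kit_a": ka, "kit_b": kb, "t": t, "p": p}
    class_tests: dict[str, dict[str, float]] = {}
    pooled = {
        cls: np.concatenate([np.asarray(v, float) for v in kits.values()])
        for cls, kits in depth_by_class.items()
    }
    classes = sorted(pooled)
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            if len(pooled[ca]) >= 2 and len(pooled[cb]) >= 2:
                t, p = _two_sample_t(pooled[ca], pooled[cb], welch)
                class_tests[f"{ca}_vs_{cb}"] = {"t": t, "p": p}
    return {"summary": summary, "kit_tests": kit_tests, "class_tests": class_tests}


def proportions_report(
    classified: Sequence[ClassifiedVariant],
    consensus: Mapping[tuple, str],
    allele_aware: bool = True,
) -> dict:
    """Error-type proportions over the HLFP loci plus the consensus split.

    Percentages are of the HLFP total and sum to >100 when multi-labels
    exist; single-label counts plus the multi-label count equal the HLFP
    total.
    """
    cls_summary = consensus_summary(consensus)
    by_locus: dict[tuple, set[str]] = {}
    for cv in classified:
        key = call_identity(cv.call, allele_aware)
        by_locus.setdefault(key, set()).update(cv.error_types)
    hlfp_loci = [k for k, c in consensus.items() if c == "HLFP"]
    n_hlfp = len(hlfp_loci)
    type_counts = {t: 0 for t in ERROR_TYPES}
    multi = 0
    single = 0
    unlabeled = 0
    for locus in hlfp_loci:
        types = by_locus.get(locus, set())
        for t in types:
            type_counts[t] += 1
        if len(types) >= 2:
            multi += 1
        elif len(types) == 1:
            single += 1
        else:
            unlabeled += 1
    type_percent = {t: (100.0 * n / n_hlfp if n_hlfp else 0.0) for t, n in type_counts.items()}
    return {
        "consensus": cls_summary,
        "n_hlfp": n_hlfp,
        "type_counts": type_counts,
        "type_percent": type_percent,
        "multi_label": multi,
        "multi_label_percent": 100.0 * multi / n_hlfp if n_hlfp else 0.0,
        "single_label": single,
        "unlabeled": unlabeled,
    }


def low_coverage_report(
    depth_by_locus_kit: Mapping[tuple, Mapping[str, float]],
    threshold: float = 5.0,
) -> dict:
    """Loci whose mean depth falls below ``threshold`` in a kit group,
    reported separately (insufficient coverage for calling)."""
    per_kit: dict[str, set] = {}
    for locus, kits in depth_by_locus_kit.items():
        for kit, depth in kits.items():
            if depth < threshold:
                per_kit.setdefault(kit, set()).add(locus)
    all_low = set().union(*per_kit.values()) if per_kit else set()
    shared = set.intersection(*per_kit.values()) if len(per_kit) > 1 else set()
    return {
        "threshold": threshold,
        "n_low": len(all_low),
        "per_kit": {k: len(v) for k, v in sorted(per_kit.items())},
        "shared": len(shared),
        "loci": sorted(all_low),
    }
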