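# Methods

## Scope and model

`ionaudit` audits positive variant calls from semiconductor exome
sequencing at the level of read alignments. It does not model flow-signal
physics, base quality, or the caller's internal thresholds: the unit of
analysis is the called variant together with the aligned reads that
support it, and every rule below is expressed in alignment coordinates.

## Coordinates and identity

All internal coordinates are 1-based (VCF convention); BED input is
0-based half-open and converted on read, so a BED line `(c, s, e)` covers
1-based positions `s+1..e`. The identity used for every set operation and
database lookup is the allele-aware tuple `(chrom, pos, ref, alt)` after
canonicalising the allele pair (trim the common suffix, then the common
prefix, keeping a 1-base anchor; the position advances with the prefix).
This collapses padded indel representations to one key; it deliberately
does **not** resolve the inherent ambiguity of an indel inside a repeat
run, which would require reference-aware left-alignment — both sides of a
lookup must simply use the same convention. A position-only mode
`(chrom, pos)` is available behind a flag for count conventions that
treat a multi-allelic site as one locus.

## The filter cascade

Ultrarare candidates are selected in a fixed order — CDS intersection,
dbSNP membership, 1000 Genomes exclusion, ExAC exclusion, sex-chromosome
exclusion — each step appending a trace (loci in, removed, loci out) over
distinct loci pooled across samples. The final survivor set equals the
conjunction of the five predicates (the order matters only to the
traces); a property test asserts this against brute-force set algebra.
An empty CDS region set is an error rather than an empty result, because
in practice it means a wrong file path, not a biological outcome.

## Weighted homopolymer rate

For a window decomposing into N maximal single-base runs of lengths
n₁..n_N,

    WHR = (Σ nᵢ²) / N.

Defaults: window 19 bp (9 bp either side of the variant anchor; for
indels the anchor is the VCF anchor base), threshold 2.22 with a strict
`>` comparison. Windows at contig edges are truncated, never padded —
padding would fabricate sequence; the truncated window is evaluated as
is. `N` bases are counted as length-1 runs so that Σ nᵢ = window length
holds while ambiguous bases never accrue homopolymer weight. A sweep
utility evaluates WHR across window sizes (3–251 bp) for users who want
to re-derive the window choice on their own data; the package default
simply adopts 19 bp.

The qualitative low-complexity flags operationalise "AT/GC-rich" and
"copolymer": composition fraction ≥ 0.8 for AT-rich/GC-rich, and a
two-base unit XY (X ≠ Y) repeated ≥ 4 times consecutively for the
dinucleotide flag. Both cutoffs are configuration-exposed; they are
package choices where the source material is qualitative. Requiring
X ≠ Y stops every ≥ 8 bp homopolymer from double-counting as a
dinucleotide repeat.

## The four error patterns

Classifiers are independent; a call may carry several labels or none.

**Simplicity region.** True iff the 19-bp window is WHR-rich or any
qualitative flag is set.

**SNV cluster.** A call is flagged iff it belongs to a set of ≥ 3
SNV-class calls of the same sample with positional span
(max − min + 1) ≤ 50 bp. Only SNVs count toward or receive the label.
The implementation flags all members of any qualifying window of three
consecutive sorted SNV positions; this is equivalent to the exhaustive
all-subsets definition (any qualifying subset contains a qualifying
consecutive triple), which a property test verifies on all inputs of
≤ 12 calls.

**Peripheral sequence read.** Per read, the variant is peripheral when
its distance to the nearer aligned read end is ≤ 5 (offset 1 = terminal
aligned base; soft clips do not move the terminus). The per-variant
verdict needs an aggregation rule the source material leaves open: the
default requires ≥ 80% of ALT-supporting reads to be peripheral,
matching the near-unanimous end-of-read support of the motivating
examples. Both margin and fraction are configuration knobs. No
supporting reads yields a negative verdict with explicit "no support"
evidence. The rule is monotone in the margin and antitone in the
fraction, and is tested as such.

**Base inversion.** Two forms. (a) Substitution form: a group of
adjacent SNV/MNV calls covering 2–3 contiguous reference bases whose
concatenated ALT is the reversal *or a nontrivial cyclic rotation* of
the concatenated REF. Reversal alone cannot cover the canonical
three-base example (AGC→CAG is a rotation, not a reversal), so both
relations are accepted. (b) Misalignment form: a deletion and an
insertion of the identical base string with anchors within 3 bp — the
same inversion pushed through an aligner as an indel pair. Groups must
be strictly contiguous in reference coordinates; whether one intervening
matching base should be allowed is not defined by the source material,
and the stricter reading was chosen.

## Curation and agreement

Verdicts are strictly binary FP/TP per rater per locus; the error
category a rater had in mind does not enter the merge. (FP,FP) → HLFP,
(TP,TP) → LTP, mixed → LFP. Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e
from the marginal verdict rates; the degenerate case of two constant,
identical raters is defined as κ = 1. The implementation is
cross-checked against `sklearn.metrics.cohen_kappa_score` in tests.

## Concordance and group comparisons

A flagged (HLFP or LFP) variant counts as *corrected* when the secondary
call set lacks it in every sample that carried it; a per-sample-call
mode is exposed because published variant-frequency plots can be read
either way. Singleton correction restricts to variants carried by
exactly one sample. Kit contrasts use the two-sided Student's
(equal-variance) t-test via `scipy.stats.ttest_ind`, with Welch behind a
flag; no multiple-testing correction is applied, matching the analysis
the package reproduces. Loci with mean depth < 5 in a kit group are
reported separately as insufficient-coverage loci.

## Pileup rendering

Text rendering is the primary product: one column per reference base
plus, after any base where some read carries an insertion, as many extra
columns as the longest insertion anchored there. Matches are `.`,
mismatches the read base, deletions `D`, insertion bases `I`, spacers
space; reads that do not carry an allocated insertion show spacers in
those columns, keeping the grid rectangular at full depth. Direction is
marked with `>` after the last rendered cell of a forward read and `<`
before the first cell of a reverse read, when that column exists inside
the window. Rows are ordered by (start, read id). Glyph choices for
matches and spacers are package conventions. The PNG output is a
cell-per-glyph projection of the same grid; only the text form is
golden-file tested byte for byte.

## Synthetic cohorts

The generator emulates the *structure* the audit assumes, not sequencing
physics. Each injected locus occupies its own 160-bp reference tile with
a designed 25-bp context embedded in seeded random flanks, so the 19-bp
window of every call (including both calls of a paired del/ins
inversion, anchored 3 bp apart) lies wholly inside designed sequence:

* homopolymer context (9-bp T run): window WHR = 91/11 ≈ 8.3;
* dinucleotide context ((AT)₇): window WHR = 1, copolymer-flagged — the
  simplicity sub-population *below* the WHR threshold;
* neutral contexts (incl. CG / AGC centre variants for inversions):
  WHR ≤ 1.4, no flags.

Mechanisms map to labels: homopolymer indel → simplicity; copolymer SNV
→ simplicity; copolymer clustered SNV → simplicity + SNV cluster;
clustered SNV → SNV cluster (two companion SNVs are planted ± 20 bp in
the same sample *without* dbSNP membership, so they complete the cluster
but never become candidates themselves — classification therefore runs
over full per-sample call lists while only candidate loci are emitted);
end-of-read → peripheral (all six supporting reads place the variant 3
aligned bases from an end); base inversion → MNV reversal/rotation calls
or del/ins pairs. True variants split into common (present in both
population tables, removed by the cascade) and ultrarare-true (rsID
only, retained, never flagged). Low-coverage loci get depth 3 and two
reads. Default supporting evidence is 6 ALT + 4 reference reads of 70 bp
per locus at depth ~80–120× in the call metrics.

Under these noise-free defaults every injected mechanism is recovered by
exactly its intended classifier and clean loci are never flagged; the
acceptance suite asserts this at ~2,000 candidate loci. A green recovery
test therefore establishes that the rules fire on their defining
patterns and nowhere else in a world without read noise, ambiguous
alignment, or overlapping mechanisms at one locus — it does not
establish classifier precision/recall on real, noisy alignments.

Kit profiles encode only directional differences (the newer chemistry:
fewer homopolymer-indel and inversion errors per sample, higher depth);
absolute per-sample counts are synthetic defaults, with ±1 sampling
jitter in kit-scaled mode so group comparisons see within-group
variance. The packaged count-structure fixture realises the published
totals exactly by construction — 675 loci; 393/126/156; type totals
219/172/22/19 with 39 double-labelled (so label assignments sum to 432);
simplicity splitting 158 WHR-rich + 61 copolymer; inversions as 15 MNVs
+ 2 del/ins pairs; 519 flagged with 201 corrected, 170 singletons with
85 corrected, 27 all-sample variants with 5 corrected — and the
discordant loci alternate which rater said FP, since the true rater
split is not recoverable; for the same reason no κ value is asserted for
the fixture.

All outputs are deterministic functions of (spec, seed); the end-to-end
summary is byte-stable under a fixed seed.

## Known limitations

* Reads are simulated directly as alignments; mapping ambiguity,
  base-quality decay and chimeric reads are out of scope.
* Indel normalisation handles representation padding, not repeat-run
  left-alignment.
* BAM/CRAM are not read; text SAM only (convert with `samtools view`).
* The classifier set is rule-based by design; no probabilistic scoring
  or recalibration is attempted.
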