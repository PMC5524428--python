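# ionaudit

Audit pipeline for ultrarare variant calls from semiconductor (Ion
Proton-class) exome sequencing.

## The problem

Semiconductor sequencers call variants quickly and cheaply, but their
flow-signal chemistry produces systematic artifacts — above all
homopolymer length errors — that position-based callers turn into
confident false-positive calls. The calls most at risk are the
*ultrarare* ones: variants that carry a dbSNP rsID yet appear in neither
the 1000 Genomes Project nor ExAC. A variant reported before but never
seen in large curated cohorts is more likely a recurrent platform
artifact than a private mutation.

`ionaudit` packages the full audit of such calls for bioinformaticians
reviewing multi-sample exome cohorts:

1. **Locus filtering** — reduce all per-sample calls to ultrarare
   candidate loci through a fixed cascade: CDS intersection → dbSNP
   membership → exclusion of 1000 Genomes phase 3 → exclusion of ExAC →
   exclusion of sex chromosomes, with a per-step exclusion trace.
2. **Error-pattern classification** — label each candidate call with any
   of four alignment-level error patterns:
   * *simplicity region*: low-complexity context. The core statistic is
     the weighted homopolymer rate of the 19-bp window around the call,

     WHR = (Σᵢ nᵢ²) / N,

     over the window's N maximal single-base runs of lengths nᵢ; WHR >
     2.22 marks homopolymer-rich sequence. AT/GC-rich and dinucleotide
     (copolymer) windows are flagged qualitatively.
   * *SNV cluster*: ≥ 3 SNV calls of one sample within ≤ 50 bp.
   * *peripheral sequence read*: ALT support confined to within 5
     aligned bases of read ends (≥ 80% of supporting reads).
   * *base inversion*: 2–3 adjacent bases whose ALT is the reversal or a
     cyclic rotation of the REF (CG→GC, AGC→CAG), or the misaligned
     equivalent — a deletion and insertion of the same base string
     anchored within 3 bp.
3. **Curation** — merge two raters' binary FP/TP verdicts into HLFP
   (both FP), LFP (discordant) and LTP (both TP) classes, with Cohen's κ
   for inter-rater agreement.
4. **Reporting** — concordance against a secondary (local de novo
   assembly) call set, error-type proportions, sequencing-kit contrasts
   (Student's t-test) and coverage-depth comparisons.
5. **Pileup rendering** — deterministic, insertion-aware text windows
   (81/201/501 bp) showing every overlapping read at full depth, for the
   manual review step mainstream browsers handle poorly.
6. **Synthetic cohorts** — a generator that plants each error mechanism
   in designed sequence contexts with exact ground truth, so every stage
   is testable offline.

## Worked example

Run the whole pipeline on a six-sample synthetic cohort:

```sh
audit run --out demo --seed 17
```

`demo/summary.json` then contains (abridged):

```json
"filter": {"candidates": 38,
  "trace": [{"step": "cds", "loci_in": 104, "removed": 8, "loci_out": 96},
            {"step": "rsid", "loci_in": 96, "removed": 24, "loci_out": 72},
            {"step": "t1gp", "loci_in": 72, "removed": 20, "loci_out": 52},
            {"step": "exac", "loci_in": 52, "removed": 10, "loci_out": 42},
            {"step": "sex_chromosomes", "loci_in": 42, "removed": 4, "loci_out": 38}]},
"consensus": {"counts": {"HLFP": 28, "LFP": 0, "LTP": 10}},
"proportions": {"type_counts": {"SIMPLICITY": 8, "SNV_CLUSTER": 8,
                                "PERIPHERAL": 6, "BASE_INVERSION": 6}},
"concordance": {"corrected": 28, "retained": 0, "corrected_percent": 100.0}
```

Reading it: of 104 distinct called loci, 38 survive the ultrarare
cascade (the trace shows what each step removed). The 28 injected error
loci are classified into the four patterns exactly as planted, both
simulated raters agree they are false positives (28 HLFP), the 10 true
ultrarare variants come out unlabeled (10 LTP), and the stand-in
secondary caller reproduces none of the flagged calls (100% corrected —
the noise-free demo world, not an expectation for real data).

The stages are also available individually (`audit simulate | filter |
whr | classify | consensus | report | render`), e.g.

```sh
audit simulate --out fixtures --seed 19 --paper-scale
audit filter --vcf-dir fixtures --cds fixtures/cds.bed \
      --dbsnp fixtures/dbsnp.tsv --t1gp fixtures/t1gp.tsv \
      --exac fixtures/exac.tsv --out loci.tsv --trace trace.tsv
audit render --sam fixtures/s01.sam --fasta fixtures/ref.fa \
      --locus chr1:73 --window 81 --out view.txt
```

`--paper-scale` generates the packaged 27-sample fixture whose count
structure mirrors the published audit (675 candidate loci, 393/126/156
consensus split, the Fig-3-style error-type breakdown).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the packaged fixtures from the seed, reruns the filter
cascade, the classifiers, the consensus merge, the WHR windowing and the
concordance counting, and writes the measured percentages (HLFP share,
per-type shares of HLFPs, multi-label share, WHR-rich share of
simplicity loci, corrected shares overall and among singletons) as JSON.
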