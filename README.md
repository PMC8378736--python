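# smallder

Annotation-free detection of differentially expressed small-RNA regions
from two-condition sRNA-seq alignments.

## The problem

Small RNAs — miRNAs, siRNAs, piRNAs, snoRNAs, tRNA fragments — are
routinely profiled by sRNA-seq in two-condition designs (healthy *vs*
tumor, wild type *vs* mutant). The standard workflow counts reads over
annotated loci and tests the count matrix with an NB model, which works for
miRNAs but fails for sRNA classes whose "genes" are poorly annotated or
undefined: piRNA clusters, siRNAs, degradation products. Tools designed for
long RNA-seq struggle because sRNA coverage is nothing like exon coverage —
miRNAs pile up in read-sized stacks while piRNAs spread raggedly over
kilobases.

`smallder` finds differentially expressed regions directly from the
coverage signal, with no annotation required, and reports each region with
an NB p-value and log2 fold change.

## The method

1. **Coverage.** Each BAM is reduced to per-chromosome coverage, stored
   run-length encoded and CPM-normalized. Positions whose mean coverage is
   below `min_depth` (default 10 CPM) in *both* conditions are masked.
2. **Candidate regions**, by independent strategies:
   - **HMM** — every unmasked position gets an adjusted NB p-value
     (positions with identical count vectors collapse into one test, since
     they describe the same locus); a two-state HMM (differentially
     expressed / not) over these p-values is decoded by Viterbi. Emissions
     binarize the p-value at `pt = 0.1` (the diff state emits p < pt with
     probability `ep = 0.9`); transitions default to
     `tp1 = 10⁻³` (not-diff → diff) and `tp2 = 10⁻⁶` (diff → not-diff).
     Long p = 1 stretches are skipped in O(1) per run without changing the
     decoded path. Good at short, moderately changed loci.
   - **IR** — "irreducible regions" over the log2 fold-change track
     f: above-threshold runs merge when the mean area above the threshold,
     MAAT(a,b) = Σ max(f−t, 0)/(b−a+1), stays ≥ t on both sides of every
     threshold crossing (t = 0.5 by default; opposite signs never merge).
     Parameter-free merging, good at long ragged loci.
   - **naive** (optional) — runs with |log2 FC| ≥ 0.5 merged across gaps
     ≤ 100 nt; **annotation** (optional) — intervals from a GFF3/GTF.
3. **Reconciliation.** Candidates are re-quantified (a read counts once per
   overlapping region), tested with the NB engine, BH-adjusted, and
   reconciled by *domination*: among overlapping regions (≥ 10 shared nt),
   A dominates B when p(A) < p(B); regions that both dominate and are
   dominated — the middle of any overlap chain — are discarded in a single
   pass. Regions with adjusted p ≤ 0.05 are reported.

The NB engine (used per nucleotide and per region) is the standard
two-group RNA-seq core: median-of-ratios size factors, per-feature
dispersion by moments shrunk toward an `a₀ + a₁/μ` trend, and a Wald test
on the log fold change — see `docs/methods.md` for the statistical detail.

## Worked example

`examples/01_detect_regions.py` simulates a small two-condition dataset
(240 short loci, 40 of them perturbed 2-fold, 3 replicates per condition)
and runs the detector:

```
13 differentially expressed regions at 5% FDR
              interval  methods  log2FC     adj p
        chr1:6260-6283   hmm+ir   -0.90  3.34e-02
      chr1:10400-10419   hmm+ir   -1.16  3.32e-02
      chr1:18951-18979      hmm   -1.10  3.32e-02
      ...
```

Each line is a detected interval: which strategies proposed it, its log2
fold change (second condition over first), and its BH-adjusted p-value.
Most detected loci are the strongly expressed perturbed ones — weakly
expressed 2-fold changes are statistically undetectable at this depth, so
the truth set used for benchmarking is itself defined by a per-locus NB
test (see `examples/05_benchmark.py`).

The same pipeline is available from the shell:

```sh
smallder simulate --out-dir sim --seed 42
smallder run --sample-sheet sim/samples.csv --output regions.tsv
smallder evaluate --sim-dir sim --regions regions.tsv
```

`smallder run` accepts any sample sheet CSV with columns
`FileName,SampleName,Condition` over sorted, indexed BAMs, and writes BED,
GFF3, GTF or TSV.

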