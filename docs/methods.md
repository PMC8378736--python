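# Methods

This note records the statistical model, the algorithmic choices, and the
limits of what the test suite demonstrates. Coordinates are 1-based closed
throughout the library; BED output converts to 0-based half-open at the I/O
boundary.

## Coverage model

Coverage at a base is the number of counted alignment records whose aligned
reference blocks (CIGAR M/=/X and D; N skips are not covered) span it.
Counted records are primary and mapped; secondary and supplementary records
are skipped, so a multi-mapped read contributes once, through its primary
record. The library size is the number of counted records, and per-sample
tracks are scaled to counts per million (CPM). Coverage is unstranded — a
known limitation: sense and antisense loci at the same position are merged.

Signals are stored run-length encoded (RLE) per chromosome, in canonical
form (no zero-length runs, adjacent runs differ). Multi-track operations
(condition means, fold change, the per-position count matrix) align tracks
on the union of run boundaries, so cost scales with the number of runs, not
genome length. The low-depth mask keeps a position when *either* condition
mean reaches `min_depth` (default 10 CPM); masking applies to the
CPM-scaled means, i.e. normalization precedes every other step.

The log2 fold-change track is `log2((mean_B + c)/(mean_A + c))` with a
pseudocount `c = 1` CPM (default) keeping it finite at zero coverage.
Condition labels are ordered lexicographically and the first is the
reference, as with R factors; fold changes are second-over-first.

## The NB testing engine

A deliberate approximation of the standard RNA-seq workflow, not a clone of
any one tool; it owns three stages:

- **Size factors** — median-of-ratios against the geometric-mean
  pseudo-reference, computed over features positive in all samples. When no
  such feature exists (common for per-nucleotide matrices with many zero
  stretches) the factors fall back to CPM-style column-sum scaling,
  normalized to geometric mean 1, with a warning.
- **Dispersions** — gene-wise moment estimates on normalized counts using
  the pooled within-condition variance (residual df = n − 2, so the two
  fitted group means do not deflate the estimate):
  `α̂ = (s² − μ·E[1/s])/μ²`, clamped to [10⁻⁸, 10]. A trend
  `α(μ) = a₀ + a₁/μ` is fitted by non-negative least squares over features
  with μ ≥ 1, and gene-wise values shrink toward it with weight
  `w = df/(df + 10)` on the gene-wise side — at 6+6 replicates the trend
  and the gene-wise estimate contribute equally. Zero-variance features
  stay at the lower clamp. With fewer than two replicates per condition
  only the trend is used.
- **Wald test** — the two-group log-link NB GLM is saturated in the group
  means, so each group mean is a concave 1-D ML problem solved by Newton
  iteration on log m, vectorized across features; group means are floored
  at half a normalized count so an all-zero group still yields a finite,
  strongly significant contrast rather than a degenerate one. The
  statistic is `ln(m_B/m_A)` over its standard error from the observed
  Fisher information (`w_j = s_j m/(1 + α s_j m)` per sample). The
  two-sided p-value uses a t reference with `3(n − 2)` degrees of freedom
  rather than a normal: the plug-in dispersion adds spread to the statistic
  at small n, and with trend shrinkage the dispersion estimate carries
  roughly triple the per-feature information; the moderate df absorbs this
  and converges to the normal as replication grows. Null simulations at
  the benchmark's design (6+6, α = 0.1, μ = 100) show a ~5% type-I rate
  and a uniform p histogram under this reference (see
  `tests/test_acceptance.py`). Features with all-zero counts are assigned
  p = 1 and LFC = 0. BH adjustment uses statsmodels.

Out of scope relative to full DESeq2-style engines, and intentionally so:
Cox-Reid MAP dispersion shrinkage, Cook's-distance outlier handling, LFC
priors, independent filtering, multi-factor designs. The test suite
cross-checks size factors (exact) and p-value rankings (Spearman ρ > 0.95)
against an independent implementation of the reference workflow.

### Per-nucleotide testing

Raw (unnormalized) per-sample coverage is segmented into maximal stretches
over which every sample is constant. Stretches failing the depth mask or
with cross-sample coverage sum below `nucleotide_sum_threshold` (default
10) are assigned p = 1 without testing. The remaining stretches are
collapsed by identical count vectors — nucleotides of the same expressed
locus produce byte-identical rows and describe one object — and each unique
vector is tested once. The BH family is the set of unique tested vectors;
forced p = 1 positions are not tests and are excluded from the adjustment.

## Segmentation

**HMM.** States: not-diff (0) and diff (1). Observations are binarized at
`pt`; the diff state emits p < pt with probability `ep`, the not-diff state
mirrors it (emits p < pt with probability 1 − ep) — the minimal symmetric
completion. Transitions: `P(0→1) = tp1 = 10⁻³`,
`P(1→0) = tp2 = 10⁻⁶`; the asymmetry keeps detected regions contiguous.
Start probabilities (1 − 10⁻³, 10⁻³). Because every RLE run is
constant-emission after binarization, the Viterbi recursion inside a run is
stepped only until the state-score difference reaches its fixed point
(both argmaxes at state 0), after which the rest of the run is closed in
O(1); the decoded path is exactly the dense path under the tie rule
"prefer staying, then prefer state 0" (verified against a dense decoder on
random tracks and against exhaustive path enumeration at small n).
Maximal diff-state runs are size-filtered to [18, 100 000] nt.

**IR.** For one sign of the fold change (signs are processed separately and
never merged), let g = max(f − t, 0) with threshold t and define
MAAT(a,b) = Σ g/(b − a + 1). Candidate intervals are bounded by
above-threshold runs; an interval is valid when at both endpoints q of
every internal below-threshold gap, MAAT(a,q) ≥ t and MAAT(q,b) ≥ t. With
h(x) = Σ_{u≤x} g(u) − t·x both conditions become order comparisons of h at
crossing points, so a scan over runs computes the furthest valid end per
start, pruning on the left-flank condition (monotone in the interval end);
the output is the set of maximal valid intervals, which may overlap when a
middle run bridges in both directions — reconciliation resolves such
overlaps downstream. A flag switches the area to the signed variant
Σ (f − t); rectified is the default, and the brute-force oracle in the test
suite shares whichever definition is configured. Exactness against the
oracle is checked on step functions with dyadic values, where binary
floating point makes both summation orders exact; on non-dyadic values a
knife-edge MAAT exactly equal to t can fall either side of the comparison
depending on summation order, which is immaterial in practice.

**Naive.** Maximal runs with |lfc| ≥ 0.5 (default) within the mask; runs of
the same sign separated by ≤ 100 nt merge; an opposite-sign run between two
same-sign runs blocks their merge. Size bounds apply after merging.

**Annotation.** One candidate per GFF3/GTF record, de-duplicated on
coordinates and exempt from the size filter — the user supplied those
intervals deliberately.

## Reconciliation

Candidates from all strategies are pooled (coordinate-identical candidates
merge their method tags), re-quantified — a read counts once for every
region it overlaps, so a read spanning k regions contributes k counts —
and tested with the NB engine, BH-adjusted over all candidates. Domination:
A dominates overlapping B (≥ `merge_min_overlap` = 10 shared nt) iff
p(A) < p(B), strictly — equal p-values never dominate, so coordinate
variants of the same locus proposed by different strategies usually tie and
both survive. Exactly the regions that both dominate and are dominated are
discarded, in one pass; the filter is idempotent and order-independent.
The pass runs once rather than iterating to a fixed point: in a chain
p₁ < p₂ < p₃ the middle region is discarded and the outer two are kept,
which is the intended semantics — the weaker outer region may still be a
real locus. Regions with adjusted p ≤ 0.05 are reported.

## Synthetic benchmark

The generator emulates the standard benchmark design for this problem
class at the alignment level:

- 2000 non-overlapping loci on one synthetic chromosome (~0.5 Mb),
  separated by ≥ 200 nt: 1000 miRNA-like loci (20–24 nt; every read spans
  the whole locus, giving sharp stacks) and 1000 piRNA-like loci
  (25–31 nt; reads of 24–30 nt at uniform offsets, giving ragged spread).
- Baseline expression per locus from a discrete power law P(X = x) ∝ x^−k,
  k = 1.5, truncated at 10⁴ — most loci weak, a few very strong.
- 100 up- and 100 down-regulated loci per class at 2-fold.
- 6 replicates per condition; per-locus, per-sample counts are NB with
  dispersion 0.05 around the scaled baseline. The default depth is
  500 000 reads per sample, sized so that a full five-replicate benchmark
  plus detection runs in minutes on a single core; detection quality is
  insensitive to depth well beyond this point because the truth set
  (below) is re-derived from the same alignments.
- Reads are written directly as sorted, indexed BAM records (`*` sequence),
  byte-identical under a fixed seed. No sequencing-error model and no
  read-level FASTQ/aligner round trip: the detector consumes only coverage,
  so simulating at the alignment level preserves the statistical structure
  while removing the external-genome dependency. Consequences: no mapping
  ambiguity, no soft-clipping, no strand structure — the benchmark
  demonstrates the statistical machinery, not robustness to alignment
  artifacts.

**Truth.** Loci are re-quantified from the simulated alignments and tested
per locus with the same NB engine; loci with adjusted p ≤ 5% form the
truth set. Weakly expressed perturbed loci that no coverage-based method
could detect are thereby excluded from the evaluation, as is conventional
for this benchmark.

**Evaluation.** A prediction matches a locus when ≥ 80% of either interval
overlaps the other. Each locus is scored by the lowest p-value of any
matching prediction (unmatched loci rank strictly worst); the ROC AUC is
trapezoidal with ties sharing average rank. `scripts/acceptance.py` runs
five seeds at the default design and reports the mean AUC over
5 × 2000 loci.

## Numerical and degenerate-input conventions

- Viterbi ties: prefer the incumbent predecessor (staying), then state 0;
  the final state prefers 0 on ties.
- Group-mean Newton: 30 iterations max, step clipped to ±3 on the log
  scale, convergence at |step| < 10⁻¹²; the objective is concave so this
  is safe.
- Empty candidate sets short-circuit to an empty (but valid) output file.
- `threads` is accepted for interface compatibility and currently executes
  serially; results are therefore trivially identical to single-threaded
  output, which is the documented contract for any future parallel
  implementation.
- The BED score column is −10·log10(adjusted p), capped at 1000.

## Known limitations

- Unstranded coverage; no paired-end semantics (mates count as separate
  records if both are primary).
- The NB engine's calibration is demonstrated at the benchmark design
  (6+6, moderate depth); at 2 replicates per condition the Wald test is
  approximate and dispersion estimation leans heavily on the trend.
- Domination uses strict inequality on floating-point p-values: two
  regions with mathematically equal but numerically distinct p-values
  would dominate one another.
- The benchmark's truth set depends on the simulated depth; AUC values are
  comparable across methods on the same dataset, not across depths.
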