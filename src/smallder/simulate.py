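"""Synthetic two-condition sRNA-seq benchmark.

Emulates the canonical simulation design for annotation-free sRNA
detectors: ~2000 short non-overlapping loci on a synthetic genome, split
into a miRNA-like class (sharp read stacks the size of the locus, ~22 nt)
and a piRNA-like class (24-30 nt reads spread across a slightly longer
locus, ~28 nt); per-locus baseline expression drawn from a discrete power
law (exponent k = 1.5: most loci weak, a few very strong); 100 loci per
class up- and 100 down-regulated 2-fold; six replicate samples per
condition with negative-binomial count noise.  Reads are written directly
as sorted, indexed alignments -- the detector consumes only coverage, so
the sequencing-error/aligner round trip adds nothing but runtime.

The truth set mirrors the benchmark convention: loci are re-quantified from
the simulated alignments and tested per locus with the NB engine; loci
passing a 5% FDR form the truth, so weakly expressed perturbed loci that no
method could detect are not counted against any of them.  Evaluation uses
the 80%-overlap matching rule, recall, and ROC AUC over all loci ranked by
the best p-value of any matched prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from sklearn.metrics import roc_auc_score

from .coverage import SampleRecord
from .nbtest import nb_wald_test
from .segmentation import CandidateRegion
from .selection import ScoredRegion, count_reads_in_regions

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "truth_regions",
    "regions_similar",
    "recall",
    "roc_auc",
    "benchmark_auc",
]

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]


@dataclass
class SimConfig:
    """Benchmark design parameters.

    Class 1 mimics miRNAs (locus ~22 nt, reads spanning the whole locus);
    class 2 mimics piRNAs (locus ~28 nt, 24-30 nt reads at random offsets).
    ``n_up``/``n_down`` loci per class are perturbed by ``fold_change``;
    baselines follow a discrete power law with exponent ``power_law_k``
    truncated at ``max_expression``.  ``reads_per_sample`` sets the expected
    sequencing depth; per-locus counts are NB with dispersion
    ``nb_dispersion``.  Everything is deterministic under ``seed``.
    """

    n_class1_loci: int = 1000
    n_class2_loci: int = 1000
    n_up: int = 100
    n_down: int = 100
    fold_change: float = 2.0
    power_law_k: float = 1.5
    replicates: int = 6
    reads_per_sample: int = 500_000
    nb_dispersion: float = 0.05
    seed: int = 0
    class1_length: tuple[int, int] = (20, 24)
    class2_length: tuple[int, int] = (25, 31)
    class2_read_length: tuple[int, int] = (24, 30)
    min_gap: int = 200
    max_expression: int = 10_000
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > min(self.n_class1_loci, self.n_class2_loci):
            raise ValueError("n_up + n_down exceeds class size")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.power_law_k <= 1:
            raise ValueError("power_law_k must exceed 1")


@dataclass
class SimulatedDataset:
    """Paths and truth tables of one simulated benchmark replicate."""

    genome_fasta: Path
    locus_bed: Path
    sample_sheet: Path
    samples: list[SampleRecord]
    loci: pd.DataFrame  # locus, chrom, start, end, class, baseline, fold

    @property
    def locus_regions(self) -> list[CandidateRegion]:
        return [
            CandidateRegion(r.chrom, int(r.start), int(r.end), "locus")
            for r in self.loci.itertuples()
        ]


def _power_law_baselines(rng: np.random.Generator, n: int, k: float, xmax: int):
    """Discrete power-law draws P(X = x) ~ x^-k on 1..xmax."""
    support = np.arange(1, xmax + 1, dtype=float)
    w = support**-k
    return rng.choice(support, size=n, p=w / w.sum()).astype(float)


def _write_sam_and_index(
    sam_path: Path, bam_path: Path, header: str, lines: list[str]
) -> None:
    with open(sam_path, "w") as fh:
        fh.write(header)
        if lines:
            fh.write("\n".join(lines))
            fh.write("\n")
    pysam.sort("--no-PG", "-o", str(bam_path), str(sam_path), catch_stdout=False)
    pysam.index(str(bam_path))
    sam_path.unlink()


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate genome, loci, truth table and per-sample sorted+indexed BAMs.

    Outputs under ``out_dir``: ``genome.fa``, ``loci.bed`` (0-based
    half-open), ``loci.csv`` (per-locus class, baseline, fold change),
    ``samples.csv`` (sample sheet) and one indexed BAM per sample
    (``A1..An``, ``B1..Bn``).  Byte-identical across runs with the same
    config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n1, n2 = cfg.n_class1_loci, cfg.n_class2_loci
    n_loci = n1 + n2
    classes = np.array([1] * n1 + [2] * n2)
    order = rng.permutation(n_loci)  # interleave the two classes along the genome
    classes = classes[order]

    lens = np.where(
        classes == 1,
        rng.integers(cfg.class1_length[0], cfg.class1_length[1] + 1, n_loci),
        rng.integers(cfg.class2_length[0], cfg.class2_length[1] + 1, n_loci),
    )
    gaps = cfg.min_gap + rng.integers(0, 101, n_loci)
    starts = np.cumsum(gaps + np.concatenate(([0], lens[:-1]))) + 1  # 1-based
    ends = starts + lens - 1
    genome_len = int(ends[-1] + cfg.min_gap)

    # per-class perturbation assignment
    fold = np.ones(n_loci)
    for cls in (1, 2):
        idx = np.flatnonzero(classes == cls)
        chosen = rng.choice(idx, size=cfg.n_up + cfg.n_down, replace=False)
        if cfg.fold_change > 1:
            fold[chosen[: cfg.n_up]] = cfg.fold_change
            fold[chosen[cfg.n_up:]] = 1.0 / cfg.fold_change
    baseline = _power_law_baselines(rng, n_loci, cfg.power_law_k, cfg.max_expression)

    # genome FASTA
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=genome_len)
    genome_fa = out / "genome.fa"
    with open(genome_fa, "w") as fh:
        fh.write(f">{cfg.chrom_name}\n")
        raw = seq.tobytes().decode()
        for i in range(0, genome_len, 60):
            fh.write(raw[i : i + 60] + "\n")

    loci = pd.DataFrame(
        {
            "locus": [f"locus{i + 1}" for i in range(n_loci)],
            "chrom": cfg.chrom_name,
            "start": starts,
            "end": ends,
            "class": classes,
            "baseline": baseline,
            "fold": fold,
        }
    )
    loci.to_csv(out / "loci.csv", index=False)
    locus_bed = out / "loci.bed"
    with open(locus_bed, "w") as fh:
        for r in loci.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.locus}\t0\t.\n")

    # per-sample alignments
    scale = cfg.reads_per_sample / baseline.sum()
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{cfg.chrom_name}\tLN:{genome_len}\n"
    samples: list[SampleRecord] = []
    rl_lo, rl_hi = cfg.class2_read_length
    for cond, cond_fold in (("A", np.ones(n_loci)), ("B", fold)):
        for rep in range(1, cfg.replicates + 1):
            name = f"{cond}{rep}"
            mean = scale * baseline * cond_fold
            nb_n = 1.0 / cfg.nb_dispersion
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mean))
            lines: list[str] = []
            rid = 0
            for i in np.flatnonzero(counts):
                c = int(counts[i])
                if classes[i] == 1:
                    # a miRNA-like stack: c identical locus-length reads
                    pos, rl = int(starts[i]), int(lens[i])
                    line = (
                        f"s{i}\t0\t{cfg.chrom_name}\t{pos}\t60\t{rl}M\t*\t0\t0\t*\t*"
                    )
                    lines.extend([line] * c)
                    rid += c
                else:
                    rls = np.minimum(
                        rng.integers(rl_lo, rl_hi + 1, c), int(lens[i])
                    )
                    offs = rng.integers(0, int(lens[i]) - rls + 1)
                    pos = np.sort(int(starts[i]) + offs)
                    # note: sorting positions decouples them from rls; read
                    # lengths are exchangeable so coverage statistics are
                    # unaffected, but positions must be sorted for SO:coordinate
                    for q, rl in zip(pos, rls):
                        rid += 1
                        lines.append(
                            f"r{rid}\t0\t{cfg.chrom_name}\t{q}\t60\t{rl}M\t*\t0\t0\t*\t*"
                        )
            bam = out / f"{name}.bam"
            _write_sam_and_index(out / f"{name}.sam", bam, header, lines)
            samples.append(SampleRecord(bam, name, cond))
            log.debug("wrote %s: %d reads", name, rid)

    sheet = out / "samples.csv"
    pd.DataFrame(
        {
            "FileName": [s.file_path.name for s in samples],
            "SampleName": [s.sample_name for s in samples],
            "Condition": [s.condition for s in samples],
        }
    ).to_csv(sheet, index=False)

    return SimulatedDataset(genome_fa, locus_bed, sheet, samples, loci)


def truth_regions(
    dataset: SimulatedDataset, fdr: float = 0.05
) -> tuple[list[Interval], pd.DataFrame]:
    """Truth set: loci differentially expressed at the given FDR.

    Re-quantifies every locus from the simulated alignments (a read counts
    once per locus it overlaps), runs the NB engine per locus, and keeps
    loci with adjusted p <= fdr.  Returns the truth intervals and the full
    per-locus test table.
    """
    regions = dataset.locus_regions
    cm = count_reads_in_regions(dataset.samples, regions)
    res = nb_wald_test(cm)
    table = dataset.loci.copy()
    table["p_value"] = res.p_value
    table["adj_p_value"] = res.adj_p_value
    table["log2_fold_change"] = res.log2_fold_change
    truth = [
        (r.chrom, int(r.start), int(r.end))
        for r in table.itertuples()
        if r.adj_p_value <= fdr
    ]
    return truth, table


def benchmark_auc(
    seed: int,
    cfg: SimConfig | None = None,
    fdr: float = 0.05,
    work_dir: str | Path | None = None,
) -> dict:
    """One full benchmark replicate: simulate, derive truth, detect, score.

    Simulates a dataset with ``seed``, defines the truth set at the given
    FDR, runs the detection pipeline with default parameters (HMM + IR) on
    the simulated sample sheet, and returns the ROC AUC over all loci
    together with bookkeeping counts.  Intermediate files go to
    ``work_dir`` (a temporary directory by default).
    """
    import tempfile

    from .pipeline import RunConfig, run_pipeline

    if cfg is None:
        cfg = SimConfig(seed=seed)
    else:
        from dataclasses import replace

        cfg = replace(cfg, seed=seed)

    def _run(d: Path) -> dict:
        ds = simulate_dataset(cfg, d)
        truth, table = truth_regions(ds, fdr)
        regions = run_pipeline(RunConfig(sample_sheet=ds.sample_sheet))
        all_loci = [
            (r.chrom, int(r.start), int(r.end)) for r in ds.loci.itertuples()
        ]
        auc = roc_auc(regions, truth, all_loci)
        rec = recall([r.interval for r in regions], truth) if truth else float("nan")
        return {
            "auc": auc,
            "recall": rec,
            "n_loci": len(all_loci),
            "n_truth": len(truth),
            "n_regions": len(regions),
        }

    if work_dir is not None:
        return _run(Path(work_dir))
    with tempfile.TemporaryDirectory(prefix="smallder-bench-") as td:
        return _run(Path(td))


def regions_similar(a: Interval, b: Interval) -> bool:
    """The 80%-overlap matching rule.

    True when at least 80% of a overlaps b, or at least 80% of b overlaps a
    (1-based closed intervals on the same chromosome).
    """
    if a[0] != b[0]:
        return False
    overlap = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if overlap <= 0:
        return False
    len_a = a[2] - a[1] + 1
    len_b = b[2] - b[1] + 1
    return overlap >= 0.8 * len_a or overlap >= 0.8 * len_b


def recall(
    predicted: Sequence[Interval], reference: Sequence[Interval]
) -> float:
    """TP / (TP + FN): fraction of reference intervals matched by a prediction."""
    if not reference:
        raise ValueError("recall is undefined for an empty reference set")
    hits = sum(
        1 for ref in reference if any(regions_similar(ref, p) for p in predicted)
    )
    return hits / len(reference)


def roc_auc(
    predicted: Sequence[ScoredRegion],
    truth: Sequence[Interval],
    all_loci: Sequence[Interval],
) -> float:
    """Trapezoidal ROC AUC over loci ranked by best matched p-value.

    Each locus is labelled positive when it belongs to the truth set and is
    scored by the lowest p-value of any prediction matching it under the
    80%-overlap rule; unmatched loci rank strictly worst.  Ties share the
    average rank.
    """
    truth_set = set(truth)
    y = np.array([loc in truth_set for loc in all_loci], dtype=int)
    if y.all() or not y.any():
        raise ValueError("ROC AUC undefined: truth is all-positive or all-negative")
    worst = 2.0  # p-values are <= 1, so unmatched loci rank last
    scores = np.full(len(all_loci), worst)
    if predicted:
        p_chrom = np.array([r.chromosome for r in predicted])
        p_start = np.array([r.start for r in predicted])
        p_end = np.array([r.end for r in predicted])
        p_len = p_end - p_start + 1
        p_val = np.array([r.p_value for r in predicted])
        for i, (chrom, s, e) in enumerate(all_loci):
            overlap = np.minimum(p_end, e) - np.maximum(p_start, s) + 1
            hit = (
                (p_chrom == chrom)
                & (overlap > 0)
                & ((overlap >= 0.8 * (e - s + 1)) | (overlap >= 0.8 * p_len))
            )
            if hit.any():
                scores[i] = p_val[hit].min()
    return float(roc_auc_score(y, -scores))
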