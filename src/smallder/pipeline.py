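"""End-to-end pipeline: sample sheet -> coverage -> candidates -> regions.

Data flow: load raw coverage from the BAMs, CPM-scale it, compute condition
means / log2 fold change / low-depth mask per chromosome, run the selected
segmentation strategies, pool and de-duplicate the candidates, re-quantify
and test them, apply the domination filter, and keep regions passing the
adjusted p-value threshold.  Results are written as BED, GFF3, GTF or TSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coverage import (
    CoverageSet,
    GlobalParams,
    SampleRecord,
    condition_mean,
    cpm_scale,
    load_alignments,
    log2_fold_change_track,
    low_depth_mask,
)
from .nbtest import per_nucleotide_pvalues
from .segmentation import (
    CandidateRegion,
    HmmParams,
    IrParams,
    NaiveParams,
    annotation_candidates,
    hmm_segment,
    ir_segment,
    naive_segment,
)
from .selection import (
    ScoredRegion,
    count_reads_in_regions,
    dedupe_candidates,
    domination_filter,
    score_regions,
    select_regions,
)

__all__ = ["RunConfig", "parse_sample_sheet", "run_pipeline", "write_regions"]

log = logging.getLogger(__name__)

_METHODS = ("naive", "hmm", "ir", "annotation")
_FORMATS = ("bed", "gff3", "gtf", "tsv")


@dataclass
class RunConfig:
    """Everything one detection run needs."""

    sample_sheet: Path
    output: Path | None = None
    out_format: str = "tsv"
    bam_dir: Path | None = None
    annotation: Path | None = None
    methods: tuple[str, ...] = ("hmm", "ir")
    global_params: GlobalParams = field(default_factory=GlobalParams)
    naive_params: NaiveParams = field(default_factory=NaiveParams)
    hmm_params: HmmParams = field(default_factory=HmmParams)
    ir_params: IrParams = field(default_factory=IrParams)
    threads: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one segmentation method required")
        for m in self.methods:
            if m not in _METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {_METHODS}")
        if self.out_format not in _FORMATS:
            raise ValueError(f"unknown format {self.out_format!r}")
        if "annotation" in self.methods and self.annotation is None:
            raise ValueError("method 'annotation' requires an annotation file")


def parse_sample_sheet(
    path: str | Path, bam_dir: str | Path | None = None
) -> list[SampleRecord]:
    """Read the sample sheet CSV (FileName, SampleName, Condition).

    BAM paths are resolved relative to ``bam_dir`` (default: the sheet's
    directory).  Validates: required columns present, sample names unique,
    exactly two condition levels.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"FileName", "SampleName", "Condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["SampleName"].duplicated().any():
        dup = df["SampleName"][df["SampleName"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample name {dup!r}")
    n_levels = df["Condition"].nunique()
    if n_levels != 2:
        raise ValueError(
            f"{path}: expected exactly 2 condition levels, found {n_levels}"
        )
    base = Path(bam_dir) if bam_dir is not None else path.parent
    return [
        SampleRecord(base / str(r.FileName), str(r.SampleName), str(r.Condition))
        for r in df.itertuples()
    ]


def _candidates_for_chromosome(
    cov_raw: CoverageSet,
    cov_cpm: CoverageSet,
    chrom: str,
    cfg: RunConfig,
) -> list[CandidateRegion]:
    g = cfg.global_params
    cond_a, cond_b = cov_cpm.conditions
    mask = low_depth_mask(cov_cpm, g.min_depth, chrom)
    out: list[CandidateRegion] = []
    if "naive" in cfg.methods or "ir" in cfg.methods:
        mean_a = condition_mean(cov_cpm, cond_a, chrom)
        mean_b = condition_mean(cov_cpm, cond_b, chrom)
        lfc = log2_fold_change_track(mean_a, mean_b, g.lfc_pseudocount)
        if "naive" in cfg.methods:
            out.extend(naive_segment(lfc, mask, cfg.naive_params, g))
        if "ir" in cfg.methods:
            out.extend(ir_segment(lfc, mask, cfg.ir_params, g))
    if "hmm" in cfg.methods:
        pvals = per_nucleotide_pvalues(cov_raw, mask, g, chrom)
        out.extend(hmm_segment(pvals, cfg.hmm_params, g))
    return out


def run_pipeline(cfg: RunConfig) -> list[ScoredRegion]:
    """Run detection end to end; returns the selected regions.

    Deterministic given the inputs.  Per-method candidate counts are logged
    before reconciliation.  The ``threads`` field is accepted for interface
    compatibility; execution is serial (and therefore trivially identical to
    single-threaded output).
    """
    samples = parse_sample_sheet(cfg.sample_sheet, cfg.bam_dir)
    log.info("stage coverage: %d samples", len(samples))
    cov_raw = load_alignments(samples)
    cov_cpm = cpm_scale(cov_raw)

    candidates: list[CandidateRegion] = []
    for chrom in cov_raw.chromosomes:
        candidates.extend(
            _candidates_for_chromosome(cov_raw, cov_cpm, chrom, cfg)
        )
    if "annotation" in cfg.methods:
        candidates.extend(
            annotation_candidates(cfg.annotation, cfg.global_params)
        )
    for m in cfg.methods:
        n = sum(1 for c in candidates if c.method == m)
        log.info("stage segmentation: method %s produced %d candidates", m, n)

    candidates = dedupe_candidates(candidates)
    if not candidates:
        log.info("no candidate regions; empty result")
        regions: list[ScoredRegion] = []
    else:
        log.info("stage quantification: %d pooled candidates", len(candidates))
        cm = count_reads_in_regions(samples, candidates)
        scored = score_regions(cm, candidates)
        kept = domination_filter(scored, cfg.global_params.merge_min_overlap)
        log.info(
            "stage reconciliation: %d regions survive domination filter",
            len(kept),
        )
        regions = select_regions(kept, cfg.global_params.pvalue_threshold)
    log.info("selected %d differentially expressed regions", len(regions))

    if cfg.output is not None:
        write_regions(regions, cfg.output, cfg.out_format)
    return regions


def _bed_score(adj_p: float) -> int:
    import math

    if adj_p <= 0:
        return 1000
    return min(1000, int(round(-10 * math.log10(adj_p) * 10)))  # -log10, x10, capped


def write_regions(
    regions: Sequence[ScoredRegion], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write regions as BED (0-based half-open), GFF3/GTF (1-based) or TSV.

    BED scores are ``-log10(adjusted p)`` scaled by 10 and capped at 1000;
    GFF3/GTF attributes carry p-value, adjusted p-value, log2 fold change
    and the generating methods.
    """
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "bed":
            fh.write('track name=smallder description="differentially expressed regions"\n')
            for i, r in enumerate(regions, 1):
                fh.write(
                    f"{r.chromosome}\t{r.start - 1}\t{r.end}\tregion{i}\t"
                    f"{_bed_score(r.adj_p_value)}\t.\n"
                )
        elif fmt in ("gff3", "gtf"):
            if fmt == "gff3":
                fh.write("##gff-version 3\n")
            for i, r in enumerate(regions, 1):
                common = (
                    f"{r.chromosome}\tsmallder\tsRNA_region\t{r.start}\t{r.end}\t"
                    f"{r.adj_p_value:.6g}\t.\t.\t"
                )
                methods = ",".join(sorted(r.methods))
                if fmt == "gff3":
                    attrs = (
                        f"ID=region{i};pvalue={r.p_value:.6g};"
                        f"padj={r.adj_p_value:.6g};"
                        f"log2FoldChange={r.log2_fold_change:.4f};"
                        f"methods={methods}"
                    )
                else:
                    attrs = (
                        f'gene_id "region{i}"; pvalue "{r.p_value:.6g}"; '
                        f'padj "{r.adj_p_value:.6g}"; '
                        f'log2FoldChange "{r.log2_fold_change:.4f}"; '
                        f'methods "{methods}";'
                    )
                fh.write(common + attrs + "\n")
        else:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                [
                    "chromosome",
                    "start",
                    "end",
                    "length",
                    "methods",
                    "base_mean",
                    "log2_fold_change",
                    "p_value",
                    "adj_p_value",
                ]
            )
            for r in regions:
                writer.writerow(
                    [
                        r.chromosome,
                        r.start,
                        r.end,
                        r.length,
                        ",".join(sorted(r.methods)),
                        f"{r.base_mean:.4f}",
                        f"{r.log2_fold_change:.4f}",
                        f"{r.p_value:.6g}",
                        f"{r.adj_p_value:.6g}",
                    ]
                )


def export_coverage_window(
    cov: CoverageSet, chromosome: str, start: int, end: int, path: str | Path
) -> None:
    """Plain-text per-sample coverage around a region (TSV: pos + one column
    per sample); a text stand-in for graphical region plots."""
    import numpy as np

    names = [s.sample_name for s in cov.samples]
    cols = {}
    for n in names:
        track = cov.tracks[n][chromosome]
        cols[n] = track.to_array()[start - 1 : end]
    df = pd.DataFrame(cols, index=np.arange(start, end + 1))
    df.index.name = "position"
    df.to_csv(path, sep="\t")
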