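"""From BAM alignments to normalized run-length coverage tracks.

The detector never looks at individual reads after this stage: each sample
is reduced to a per-chromosome coverage signal (number of alignment records
covering each base), stored run-length encoded, then scaled to counts per
million (CPM) so samples of different depth are comparable.

Conventions
-----------
* Coordinates are 1-based closed internally; BED output converts at the I/O
  boundary.
* Coverage is unstranded.
* Only primary, mapped alignment records are counted (secondary and
  supplementary records are skipped); a multi-mapped read's primary record
  counts once.  The library size is the number of counted records.
* CIGAR M/=/X and D operations cover the reference; N (intron skip) does
  not.  sRNA reads are short and unspliced, so this rarely matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .rle import RunLengthTrack, merge_tracks

__all__ = [
    "SampleRecord",
    "GlobalParams",
    "CoverageSet",
    "load_alignments",
    "cpm_scale",
    "condition_mean",
    "log2_fold_change_track",
    "low_depth_mask",
]

log = logging.getLogger(__name__)

_SKIP_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary

# CIGAR operation codes that consume the reference and are covered (M, =, X, D)
_COVERED_OPS = {0, 7, 8, 2}
# N: consumes reference but is not covered
_REF_SKIP = 3


@dataclass(frozen=True)
class SampleRecord:
    """One row of the sample sheet: a BAM file, its sample name, its condition."""

    file_path: Path
    sample_name: str
    condition: str


@dataclass
class GlobalParams:
    """Parameters shared by every stage of the detector.

    min_depth
        Positions where the mean CPM coverage is below this value in *both*
        conditions are masked out of all downstream analysis (default 10).
    min_size, max_size
        Size bounds on emitted candidate regions, in nucleotides
        (defaults 18 and 100 000, spanning miRNA-sized to long piRNA-cluster
        sized loci).
    nucleotide_sum_threshold
        Positions whose raw coverage summed over all samples is below this
        are assigned a p-value of 1 instead of being tested (default 10).
    merge_min_overlap
        Minimum number of shared nucleotides for two candidate regions to be
        considered overlapping during reconciliation (default 10).
    pvalue_threshold
        Adjusted p-value cut-off for the final region list (default 0.05).
    lfc_pseudocount
        Pseudocount, in CPM units, added to both condition means before
        taking the log2 ratio so the fold-change track is finite (default 1).
    """

    min_depth: float = 10.0
    min_size: int = 18
    max_size: int = 100_000
    nucleotide_sum_threshold: float = 10.0
    merge_min_overlap: int = 10
    pvalue_threshold: float = 0.05
    lfc_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")
        if not 0 < self.pvalue_threshold <= 1:
            raise ValueError("pvalue_threshold must be in (0, 1]")
        for name in ("min_depth", "nucleotide_sum_threshold", "lfc_pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CoverageSet:
    """Per-sample run-length coverage tracks over a shared chromosome set."""

    samples: list[SampleRecord]
    chrom_lengths: dict[str, int]
    tracks: dict[str, dict[str, RunLengthTrack]]  # sample -> chrom -> track
    library_sizes: dict[str, int]
    normalized: bool = False

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def conditions(self) -> list[str]:
        """The condition labels, sorted; the first is the reference level
        (fold changes are second over first)."""
        return sorted({s.condition for s in self.samples})

    @property
    def cpm_factors(self) -> dict[str, float]:
        return {name: 1e6 / size for name, size in self.library_sizes.items()}

    def samples_in(self, condition: str) -> list[SampleRecord]:
        out = [s for s in self.samples if s.condition == condition]
        if not out:
            raise ValueError(f"unknown condition label: {condition!r}")
        return out


def _covered_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """0-based half-open reference blocks covered by an alignment record."""
    cig = read.cigartuples
    pos = read.reference_start
    if cig is None:
        return []
    if len(cig) == 1 and cig[0][0] == 0:  # plain M: the common sRNA case
        return [(pos, pos + cig[0][1])]
    blocks: list[tuple[int, int]] = []
    start = pos
    for op, n in cig:
        if op in _COVERED_OPS:
            pos += n
        elif op == _REF_SKIP:
            if pos > start:
                blocks.append((start, pos))
            pos += n
            start = pos
        # insertions / clips do not consume the reference
    if pos > start:
        blocks.append((start, pos))
    return blocks


def load_alignments(
    samples: Sequence[SampleRecord] | Sequence[str | Path],
    chromosomes: Iterable[str] | None = None,
) -> CoverageSet:
    """Compute raw per-sample coverage tracks from sorted, indexed BAM files.

    ``samples`` may be SampleRecords or bare paths (sample name defaults to
    the file stem, condition to ``""``).  Coverage at a base is the number of
    counted alignment records whose aligned reference blocks span it.

    Raises
    ------
    FileNotFoundError
        If a BAM file is missing or unreadable.
    ValueError
        If a sample contains no counted alignment record (its library size,
        hence its CPM scale, would be undefined).
    """
    records: list[SampleRecord] = []
    for s in samples:
        if isinstance(s, SampleRecord):
            records.append(s)
        else:
            p = Path(s)
            records.append(SampleRecord(p, p.stem, ""))
    if not records:
        raise ValueError("no samples given")

    wanted = set(chromosomes) if chromosomes is not None else None
    chrom_lengths: dict[str, int] = {}
    tracks: dict[str, dict[str, RunLengthTrack]] = {}
    library_sizes: dict[str, int] = {}

    for rec in records:
        path = Path(rec.file_path)
        if not path.exists():
            raise FileNotFoundError(f"alignment file not found: {path}")
        with pysam.AlignmentFile(str(path)) as af:
            names = af.references
            lengths = af.lengths
            sel = {
                n: l for n, l in zip(names, lengths) if wanted is None or n in wanted
            }
            if not chrom_lengths:
                chrom_lengths.update(sel)
            elif sel != chrom_lengths:
                raise ValueError(
                    f"{path}: chromosome set differs from previous samples"
                )
            diffs = {c: np.zeros(l + 1, dtype=np.int64) for c, l in sel.items()}
            n_counted = 0
            for read in af.fetch(until_eof=True):
                if read.flag & _SKIP_FLAGS:
                    continue
                chrom = read.reference_name
                if chrom not in diffs:
                    continue
                n_counted += 1
                d = diffs[chrom]
                for s0, e0 in _covered_blocks(read):
                    d[s0] += 1
                    d[min(e0, d.size - 1)] -= 1
        if n_counted == 0:
            raise ValueError(
                f"{path}: no counted alignment records; library size undefined"
            )
        library_sizes[rec.sample_name] = n_counted
        tracks[rec.sample_name] = {
            c: RunLengthTrack.from_array(c, np.cumsum(d[:-1])) for c, d in diffs.items()
        }
        log.debug("loaded %s: %d records", rec.sample_name, n_counted)

    return CoverageSet(records, chrom_lengths, tracks, library_sizes)


def cpm_scale(cov: CoverageSet) -> CoverageSet:
    """Scale every track to counts per million of its sample's library size."""
    factors = cov.cpm_factors
    scaled = {
        name: {c: t.map(lambda v, f=factors[name]: v * f) for c, t in per.items()}
        for name, per in cov.tracks.items()
    }
    return CoverageSet(
        cov.samples, dict(cov.chrom_lengths), scaled, dict(cov.library_sizes),
        normalized=True,
    )


def condition_mean(
    cov: CoverageSet, condition: str, chromosome: str
) -> RunLengthTrack:
    """Position-wise mean coverage across the samples of one condition."""
    names = [s.sample_name for s in cov.samples_in(condition)]
    return merge_tracks(
        [cov.tracks[n][chromosome] for n in names], lambda m: m.mean(axis=0)
    )


def log2_fold_change_track(
    mean_a: RunLengthTrack, mean_b: RunLengthTrack, pseudocount: float = 1.0
) -> RunLengthTrack:
    """log2((mean_b + pc) / (mean_a + pc)) per position; finite everywhere."""
    return merge_tracks(
        [mean_a, mean_b],
        lambda m: np.log2((m[1] + pseudocount) / (m[0] + pseudocount)),
    )


def low_depth_mask(
    cov: CoverageSet, min_depth: float, chromosome: str
) -> RunLengthTrack:
    """Boolean track: 1 where at least one condition mean reaches min_depth.

    A position is discarded (mask 0) only when its mean CPM coverage is below
    ``min_depth`` in *both* conditions; masked positions are excluded from
    candidate generation and from per-nucleotide testing.
    """
    if not cov.normalized:
        raise ValueError("low_depth_mask expects a CPM-scaled CoverageSet")
    conds = cov.conditions
    means = [condition_mean(cov, c, chromosome) for c in conds]
    return merge_tracks(
        means, lambda m: (m.max(axis=0) >= min_depth).astype(float)
    )
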