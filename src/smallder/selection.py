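"""Reconciliation of candidate regions.

Candidates from the different strategies overlap.  Each candidate is
re-quantified from the original alignments (a read counts once for every
region it overlaps), tested for differential expression with the NB engine,
and the overlaps are resolved by the *domination* rule: among overlapping
regions, region A dominates region B when A's p-value is strictly smaller.
Exactly the regions that are simultaneously dominated by some overlapping
region and dominating another are discarded -- the "middle" of any chain of
overlaps -- in a single pass.  Equal p-values never dominate, so ties
survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from .coverage import SampleRecord, _SKIP_FLAGS
from .nbtest import CountMatrix, nb_wald_test
from .segmentation import CandidateRegion

__all__ = [
    "ScoredRegion",
    "count_reads_in_regions",
    "score_regions",
    "domination_filter",
    "select_regions",
]

log = logging.getLogger(__name__)


@dataclass
class ScoredRegion:
    """A candidate interval with counts and differential-expression scores."""

    chromosome: str
    start: int  # 1-based closed
    end: int
    methods: frozenset[str]
    counts: np.ndarray
    base_mean: float = 0.0
    log2_fold_change: float = 0.0
    p_value: float = 1.0
    adj_p_value: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


def dedupe_candidates(candidates: Sequence[CandidateRegion]) -> list[CandidateRegion]:
    """Collapse coordinate-identical candidates, merging their method tags."""
    by_coord: dict[tuple[str, int, int], set[str]] = {}
    for c in candidates:
        by_coord.setdefault((c.chromosome, c.start, c.end), set()).add(c.method)
    return [
        CandidateRegion(chrom, s, e, "+".join(sorted(methods)))
        for (chrom, s, e), methods in sorted(by_coord.items())
    ]


def count_reads_in_regions(
    samples: Sequence[SampleRecord],
    regions: Sequence[CandidateRegion],
) -> CountMatrix:
    """Region x sample read counts.

    Cell (r, s) is the number of counted alignment records of sample s whose
    alignment span overlaps region r by at least one nucleotide; a record
    overlapping k regions contributes to all k.  The same record filter as
    the coverage step applies (primary, mapped).
    """
    if not regions:
        raise ValueError("no regions to quantify")
    counts = np.zeros((len(regions), len(samples)), dtype=float)
    for j, rec in enumerate(samples):
        with pysam.AlignmentFile(str(rec.file_path)) as af:
            for i, reg in enumerate(regions):
                n = 0
                for read in af.fetch(reg.chromosome, reg.start - 1, reg.end):
                    if not read.flag & _SKIP_FLAGS:
                        n += 1
                counts[i, j] = n
    conditions = np.asarray([s.condition for s in samples])
    ids = np.asarray([f"{r.chromosome}:{r.start}-{r.end}" for r in regions])
    return CountMatrix(counts, conditions, ids)


def score_regions(
    cm: CountMatrix, regions: Sequence[CandidateRegion]
) -> list[ScoredRegion]:
    """NB Wald test per region; BH adjustment over all candidate regions."""
    res = nb_wald_test(cm)
    out = []
    for i, reg in enumerate(regions):
        out.append(
            ScoredRegion(
                reg.chromosome,
                reg.start,
                reg.end,
                frozenset(reg.method.split("+")),
                cm.counts[i],
                base_mean=float(res.base_mean[i]),
                log2_fold_change=float(res.log2_fold_change[i]),
                p_value=float(res.p_value[i]),
                adj_p_value=float(res.adj_p_value[i]),
            )
        )
    return out


def domination_filter(
    regions: Sequence[ScoredRegion], min_overlap: int = 10
) -> list[ScoredRegion]:
    """Discard regions that both dominate and are dominated.

    Two regions overlap when they share at least ``min_overlap`` nucleotides.
    A dominates B iff p(A) < p(B) (strict: ties never dominate).  The filter
    is a single pass (non-iterative), is idempotent, and is independent of
    input order.
    """
    order = sorted(range(len(regions)), key=lambda i: regions[i].interval)
    dominates = [False] * len(regions)
    dominated = [False] * len(regions)
    for a in range(len(order)):
        i = order[a]
        ri = regions[i]
        for b in range(a + 1, len(order)):
            j = order[b]
            rj = regions[j]
            if rj.chromosome != ri.chromosome or rj.start > ri.end - min_overlap + 1:
                break
            overlap = min(ri.end, rj.end) - max(ri.start, rj.start) + 1
            if overlap < min_overlap:
                continue
            if ri.p_value < rj.p_value:
                dominates[i] = True
                dominated[j] = True
            elif rj.p_value < ri.p_value:
                dominates[j] = True
                dominated[i] = True
    return [
        r
        for k, r in enumerate(regions)
        if not (dominates[k] and dominated[k])
    ]


def select_regions(
    scored: Sequence[ScoredRegion], threshold: float
) -> list[ScoredRegion]:
    """Regions with adjusted p-value <= threshold, sorted by coordinate."""
    out = [r for r in scored if r.adj_p_value <= threshold]
    out.sort(key=lambda r: (r.chromosome, r.start, r.end))
    return out
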