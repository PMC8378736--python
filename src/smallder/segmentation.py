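"""Candidate-region generation.

Three independent strategies turn per-chromosome signal tracks into lists of
putative differentially expressed intervals, each tuned to a different sRNA
expression profile:

* ``naive_segment`` -- threshold the log2 fold-change track and merge
  nearby same-sign runs; simple, needs a merge-distance parameter.
* ``hmm_segment`` -- decode a two-state hidden Markov model over the
  per-nucleotide adjusted p-value track (states: differentially expressed /
  not); good at short, moderately changed loci such as miRNAs.
* ``ir_segment`` -- "irreducible regions": merge above-threshold
  fold-change runs whenever the mean area above the threshold (MAAT) stays
  high across every crossing point; good at long, ragged loci such as piRNA
  clusters, with no distance parameter.

An optional annotation file contributes a fourth candidate list.  All
coordinates are 1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log, log1p
from pathlib import Path

import numpy as np

from .coverage import GlobalParams
from .rle import RunLengthTrack, segment_table

__all__ = [
    "NaiveParams",
    "HmmParams",
    "IrParams",
    "CandidateRegion",
    "naive_segment",
    "viterbi_two_state",
    "hmm_segment",
    "ir_segment",
    "annotation_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class NaiveParams:
    """min_log_fold_change: |log2 FC| threshold; max_distance: merge gap (nt)."""

    min_log_fold_change: float = 0.5
    max_distance: int = 100

    def __post_init__(self) -> None:
        if self.min_log_fold_change < 0 or self.max_distance < 0:
            raise ValueError("naive parameters must be non-negative")


@dataclass
class HmmParams:
    """Two-state HMM parameters.

    tp1
        Transition probability not-diff -> diff (default 0.001).
    tp2
        Transition probability diff -> not-diff (default 1e-6); tp2 << tp1
        keeps detected regions contiguous.
    pt
        p-value threshold below which an observation counts as "significant"
        (default 0.1).  Emissions depend only on this binarization.
    ep
        Probability that the diff state emits a significant p-value
        (default 0.9); the not-diff state mirrors it (emits significant with
        probability 1 - ep).
    start_prob_diff
        Initial probability of the diff state (default 0.001).
    """

    tp1: float = 0.001
    tp2: float = 0.000001
    pt: float = 0.1
    ep: float = 0.9
    start_prob_diff: float = 0.001

    def __post_init__(self) -> None:
        for name in ("tp1", "tp2", "pt", "ep", "start_prob_diff"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1)")


@dataclass
class IrParams:
    """min_log_fold_change: the MAAT threshold t (default 0.5)."""

    min_log_fold_change: float = 0.5

    def __post_init__(self) -> None:
        if self.min_log_fold_change <= 0:
            raise ValueError("min_log_fold_change must be positive")


@dataclass(frozen=True)
class CandidateRegion:
    """A putative differentially expressed interval (1-based closed)."""

    chromosome: str
    start: int
    end: int
    method: str
    sign: str | None = None  # '+'/'-' of the fold change; None for hmm/annotation

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _size_filter(
    regions: list[CandidateRegion], g: GlobalParams
) -> list[CandidateRegion]:
    return [r for r in regions if g.min_size <= r.length <= g.max_size]


# ---------------------------------------------------------------------------
# naive


def naive_segment(
    lfc: RunLengthTrack,
    mask: RunLengthTrack,
    p: NaiveParams,
    g: GlobalParams,
) -> list[CandidateRegion]:
    """Threshold-and-merge segmentation of the log2 fold-change track.

    Maximal runs with ``|lfc| >= min_log_fold_change`` (within the mask) are
    kept; same-sign runs separated by at most ``max_distance`` nucleotides
    are merged.  Runs of opposite sign are never merged, and an
    opposite-sign run between two same-sign runs blocks their merge.  Size
    bounds are applied after merging.
    """
    lengths, values = segment_table([lfc, mask])
    vals = np.where(values[:, 1] > 0, values[:, 0], 0.0)
    flag = np.abs(vals) >= p.min_log_fold_change
    ends = np.cumsum(lengths)
    starts = ends - lengths

    # maximal same-sign super-threshold runs
    runs: list[tuple[int, int, int]] = []  # (start, end, sign) 1-based
    for i in range(lengths.size):
        if not flag[i]:
            continue
        sign = 1 if vals[i] > 0 else -1
        s, e = int(starts[i]) + 1, int(ends[i])
        if runs and runs[-1][1] == s - 1 and runs[-1][2] == sign:
            runs[-1] = (runs[-1][0], e, sign)
        else:
            runs.append((s, e, sign))

    merged: list[tuple[int, int, int]] = []
    for s, e, sign in runs:
        if merged and sign == merged[-1][2] and s - merged[-1][1] - 1 <= p.max_distance:
            merged[-1] = (merged[-1][0], e, sign)
        else:
            merged.append((s, e, sign))

    out = [
        CandidateRegion(lfc.chromosome, s, e, "naive", "+" if sign > 0 else "-")
        for s, e, sign in merged
    ]
    return _size_filter(out, g)


# ---------------------------------------------------------------------------
# HMM


def viterbi_two_state(
    observations: RunLengthTrack | list[tuple[float, int]],
    p: HmmParams,
) -> list[tuple[int, int]]:
    """Most likely state path over a run-length p-value sequence.

    States are 0 (not differentially expressed) and 1 (differentially
    expressed).  Observations are binarized at ``pt``, so every input run is
    constant-emission; within such a run the Viterbi recursion is stepped
    only until the score difference between the states reaches its fixed
    point (both states' best predecessor is state 0 and the difference is
    the constant ``log tp1 + e1 - log(1-tp1) - e0``), after which the rest
    of the run is closed in O(1).  The long stretches of p = 1 that dominate
    a genome are therefore skipped, yet the returned path is exactly the
    dense Viterbi path (ties broken toward staying, then toward state 0).

    Returns the path as ``(state, run_length)`` pairs.
    """
    if isinstance(observations, RunLengthTrack):
        pairs = list(zip(observations.values.tolist(), observations.lengths.tolist()))
    else:
        pairs = [(float(v), int(n)) for v, n in observations]
    if any(not 0 <= v <= 1 for v, _ in pairs):
        raise ValueError("observations must be p-values in [0, 1]")
    # binarize and refuse empty input
    runs: list[tuple[int, int]] = []
    for v, n in pairs:
        if n <= 0:
            continue
        b = 1 if v < p.pt else 0
        if runs and runs[-1][0] == b:
            runs[-1] = (b, runs[-1][1] + n)
        else:
            runs.append((b, n))
    if not runs:
        return []

    t00, t01 = log1p(-p.tp1), log(p.tp1)
    t10, t11 = log(p.tp2), log1p(-p.tp2)
    e0 = (log(p.ep), log1p(-p.ep))  # not-diff emits b=0 w.p. ep
    e1 = (log1p(-p.ep), log(p.ep))  # diff emits b=1 w.p. ep
    d_star = (t01 + e1[0] - t00 - e0[0], t01 + e1[1] - t00 - e0[1])
    stable = tuple(
        t00 >= d_star[b] + t10 and t01 >= d_star[b] + t11 for b in (0, 1)
    )

    # records: ('s', bp0, bp1) = one dense step; ('k', m) = m skipped steps
    records: list[tuple] = []
    b0, L0 = runs[0]
    s0 = log1p(-p.start_prob_diff) + e0[b0]
    s1 = log(p.start_prob_diff) + e1[b0]
    first = True
    for b, L in runs:
        i = 1 if first else 0  # first position already consumed by the start
        first = False
        while i < L:
            pick00 = s0 + t00 >= s1 + t10
            pick01 = s0 + t01 >= s1 + t11
            if pick00 and pick01 and stable[b]:
                rem = L - i
                records.append(("k", rem))
                s0 += rem * (t00 + e0[b])
                s1 = s0 + d_star[b]
                break
            n0 = (s0 + t00 if pick00 else s1 + t10) + e0[b]
            n1 = (s0 + t01 if pick01 else s1 + t11) + e1[b]
            records.append(("s", 0 if pick00 else 1, 0 if pick01 else 1))
            s0, s1 = n0, n1
            i += 1

    # backtrack, emitting states newest-first
    state = 0 if s0 >= s1 else 1
    rev: list[tuple[int, int]] = []

    def emit(st: int, n: int) -> None:
        if rev and rev[-1][0] == st:
            rev[-1] = (st, rev[-1][1] + n)
        else:
            rev.append((st, n))

    for rec in reversed(records):
        if rec[0] == "s":
            emit(state, 1)
            state = rec[1 + state]
        else:  # skipped block: every backpointer is state 0
            m = rec[1]
            emit(state, 1)
            if m > 1:
                emit(0, m - 1)
            state = 0
    emit(state, 1)  # the first position
    rev.reverse()
    return rev


def hmm_segment(
    pvals: RunLengthTrack, p: HmmParams, g: GlobalParams
) -> list[CandidateRegion]:
    """Size-filtered maximal diff-state runs of the Viterbi path."""
    path = viterbi_two_state(pvals, p)
    out: list[CandidateRegion] = []
    pos = 0
    for state, n in path:
        if state == 1:
            out.append(CandidateRegion(pvals.chromosome, pos + 1, pos + n, "hmm"))
        pos += n
    return _size_filter(out, g)


# ---------------------------------------------------------------------------
# irreducible regions


def _ir_one_sign(
    chromosome: str,
    seg_lengths: np.ndarray,
    f: np.ndarray,
    t: float,
    signed_area: bool,
) -> list[tuple[int, int]]:
    """Merged intervals for one fold-change sign.

    ``f`` is the sign-rectified fold change per aligned segment (0 where
    masked or of the opposite sign).  Works on the crossing points only:
    above-threshold runs r_i = [s_i, e_i]; an interval spanning runs i..j is
    valid when, at both endpoints q of every internal below-threshold gap,
    MAAT(s_i, q) >= t and MAAT(q, e_j) >= t, where
    MAAT(a, b) = area(a, b) / (b - a + 1) and the area is the (rectified,
    or signed when ``signed_area``) excess of f over t.  Returned intervals
    are the maximal valid ones.
    """
    ends = np.cumsum(seg_lengths)
    starts = ends - seg_lengths
    above = f >= t

    runs: list[tuple[int, int]] = []
    for i in range(seg_lengths.size):
        if not above[i]:
            continue
        s, e = int(starts[i]) + 1, int(ends[i])
        if runs and runs[-1][1] == s - 1:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))
    if not runs:
        return []
    m = len(runs)
    if m == 1:
        return runs

    # prefix area at position granularity: P(x) = sum_{u<=x} g(u)
    gseg = (f - t) if signed_area else np.maximum(f - t, 0.0)
    cum = np.concatenate(([0.0], np.cumsum(gseg * seg_lengths)))

    def prefix(x: int) -> float:
        """P(x) for 0 <= x <= total length."""
        if x <= 0:
            return 0.0
        i = int(np.searchsorted(ends, x, side="left"))
        return float(cum[i] + (x - starts[i]) * gseg[i])

    def h(x: int) -> float:
        return prefix(x) - t * x

    rs = np.array([r[0] for r in runs])
    re = np.array([r[1] for r in runs])
    # per internal gap k (between run k and k+1): crossing points are the
    # gap's two endpoints (coincident for 1-nt gaps)
    q_hmin = np.empty(m - 1)  # min h over the gap's crossing points
    qm_hmax = np.empty(m - 1)  # max h over the points just before a crossing
    for k in range(m - 1):
        q1, q2 = int(re[k]) + 1, int(rs[k + 1]) - 1
        q_hmin[k] = min(h(q1), h(q2))
        qm_hmax[k] = max(h(q1 - 1), h(q2 - 1))

    h_start = np.array([h(int(s) - 1) for s in rs])
    h_end = np.array([h(int(e)) for e in re])

    # furthest valid end M(i) per start; the left-flank constraint is
    # monotone in j, so the scan stops at its first violation
    best_end = np.arange(m)
    for i in range(m):
        lo = np.inf
        hi = -np.inf
        for j in range(i + 1, m):
            lo = min(lo, q_hmin[j - 1])
            hi = max(hi, qm_hmax[j - 1])
            # MAAT(a,q) >= t  <=>  h(q) >= h(a-1); MAAT(q,b) >= t <=> h(b) >= h(q-1)
            if lo < h_start[i]:
                break
            if h_end[j] >= hi:
                best_end[i] = j

    out: list[tuple[int, int]] = []
    seen = -1
    for i in range(m):
        if best_end[i] > seen:
            out.append((int(rs[i]), int(re[best_end[i]])))
            seen = best_end[i]
    return out


def ir_segment(
    lfc: RunLengthTrack,
    mask: RunLengthTrack,
    p: IrParams,
    g: GlobalParams,
    signed_area: bool = False,
) -> list[CandidateRegion]:
    """Irreducible-region segmentation of the log2 fold-change track.

    Positive and negative fold changes are processed separately (regions of
    opposite sign are never merged).  ``signed_area`` switches the MAAT area
    from the default rectified ``max(f - t, 0)`` to the signed ``f - t``.
    """
    t = p.min_log_fold_change
    lengths, values = segment_table([lfc, mask])
    out: list[CandidateRegion] = []
    for sign, tag in ((1.0, "+"), (-1.0, "-")):
        f = np.where(values[:, 1] > 0, sign * values[:, 0], 0.0)
        f = np.maximum(f, 0.0)
        for s, e in _ir_one_sign(lfc.chromosome, lengths, f, t, signed_area):
            out.append(CandidateRegion(lfc.chromosome, s, e, "ir", tag))
    out.sort(key=lambda r: (r.start, r.end))
    return _size_filter(out, g)


# ---------------------------------------------------------------------------
# annotation


def annotation_candidates(
    gff_path: str | Path, g: GlobalParams
) -> list[CandidateRegion]:
    """Candidate intervals from a GFF3/GTF annotation of known sRNA loci.

    One candidate per record, de-duplicated on coordinates.  Annotation
    candidates are exempt from the size filter: the user supplied them
    deliberately.
    """
    import pyranges as pr

    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    with open(path) as fh:
        has_data = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_data:
        return []
    reader = pr.read_gtf if path.suffix.lower() == ".gtf" else pr.read_gff3
    try:
        df = reader(str(path)).df
    except Exception as exc:  # pragma: no cover - exercised via malformed input
        raise ValueError(f"malformed annotation file {path}: {exc}") from exc
    if df.empty:
        return []
    seen: set[tuple[str, int, int]] = set()
    out: list[CandidateRegion] = []
    for chrom, start0, end in zip(df["Chromosome"], df["Start"], df["End"]):
        key = (str(chrom), int(start0) + 1, int(end))
        if key in seen:
            continue
        seen.add(key)
        out.append(CandidateRegion(key[0], key[1], key[2], "annotation"))
    out.sort(key=lambda r: (r.chromosome, r.start, r.end))
    return out
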