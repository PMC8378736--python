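"""Run-length encoded genome tracks.

A genome-length signal (coverage, log2 fold change, p-values, masks) is
stored per chromosome as a sequence of ``(value, length)`` runs.  Small-RNA
coverage is zero over the vast majority of the genome, so the run-length
representation keeps whole-genome signals in a few thousand runs instead of
megabase-sized dense arrays, and lets downstream passes (segmentation,
Viterbi decoding) work per run instead of per nucleotide.

Tracks are kept in *canonical* form: no zero-length runs, and adjacent runs
always carry distinct values.  ``encode(decode(t)) == t`` for any canonical
track.
"""

from __future__ import annotations

from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = ["RunLengthTrack", "merge_tracks", "segment_table"]


class RunLengthTrack:
    """A per-chromosome signal stored as (value, run-length) pairs.

    Parameters
    ----------
    chromosome
        Chromosome name the track belongs to.
    values, lengths
        Parallel arrays of run values (float) and run lengths (positive int).
        The input is canonicalised: zero-length runs are dropped and adjacent
        equal-valued runs merged.
    """

    __slots__ = ("chromosome", "values", "lengths")

    def __init__(self, chromosome: str, values, lengths) -> None:
        values = np.asarray(values, dtype=float)
        lengths = np.asarray(lengths, dtype=np.int64)
        if values.shape != lengths.shape or values.ndim != 1:
            raise ValueError("values and lengths must be parallel 1-D arrays")
        if np.any(lengths < 0):
            raise ValueError("run lengths must be non-negative")
        keep = lengths > 0
        values, lengths = values[keep], lengths[keep]
        if values.size:
            # merge adjacent runs with identical values (canonical form)
            boundary = np.empty(values.size, dtype=bool)
            boundary[0] = True
            boundary[1:] = values[1:] != values[:-1]
            idx = np.flatnonzero(boundary)
            values = values[idx]
            lengths = np.add.reduceat(lengths, idx)
        self.chromosome = chromosome
        self.values = values
        self.lengths = lengths

    # -- basic protocol ----------------------------------------------------

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    @property
    def starts(self) -> np.ndarray:
        """0-based start offset of each run."""
        return np.concatenate(([0], np.cumsum(self.lengths)[:-1]))

    @property
    def ends(self) -> np.ndarray:
        """0-based exclusive end offset of each run."""
        return np.cumsum(self.lengths)

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self) -> Iterator[tuple[float, int]]:
        return zip(self.values.tolist(), self.lengths.tolist())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RunLengthTrack)
            and self.chromosome == other.chromosome
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.lengths, other.lengths)
        )

    def __repr__(self) -> str:
        return (
            f"RunLengthTrack({self.chromosome!r}, {len(self)} runs, "
            f"{self.total_length} nt)"
        )

    # -- encode / decode ---------------------------------------------------

    @classmethod
    def from_array(cls, chromosome: str, arr) -> "RunLengthTrack":
        """Encode a dense per-position vector."""
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            return cls(chromosome, [], [])
        boundary = np.empty(arr.size, dtype=bool)
        boundary[0] = True
        boundary[1:] = arr[1:] != arr[:-1]
        idx = np.flatnonzero(boundary)
        lengths = np.diff(np.append(idx, arr.size))
        return cls(chromosome, arr[idx], lengths)

    def to_array(self) -> np.ndarray:
        """Decode to a dense per-position vector."""
        return np.repeat(self.values, self.lengths)

    # -- transforms --------------------------------------------------------

    def map(self, func: Callable[[np.ndarray], np.ndarray]) -> "RunLengthTrack":
        """Apply an elementwise function to the run values."""
        return RunLengthTrack(self.chromosome, func(self.values), self.lengths)

    def value_at(self, offset: int) -> float:
        """Value at a 0-based position offset."""
        if not 0 <= offset < self.total_length:
            raise IndexError(offset)
        i = np.searchsorted(self.ends, offset, side="right")
        return float(self.values[i])

    def intervals_where(self, predicate) -> list[tuple[int, int]]:
        """1-based closed intervals of maximal runs where ``predicate(value)``.

        Canonical form guarantees maximality after merging adjacent
        predicate-true runs.
        """
        flag = np.asarray(predicate(self.values), dtype=bool)
        out: list[tuple[int, int]] = []
        starts, ends = self.starts, self.ends
        i = 0
        n = len(self)
        while i < n:
            if flag[i]:
                j = i
                while j + 1 < n and flag[j + 1]:
                    j += 1
                out.append((int(starts[i]) + 1, int(ends[j])))
                i = j + 1
            else:
                i += 1
        return out


def _aligned_values(tracks: Sequence[RunLengthTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Align several equal-length tracks on the union of run boundaries.

    Returns ``(lengths, matrix)`` where ``matrix[k, s]`` is the value of
    track ``k`` on aligned segment ``s``.
    """
    total = tracks[0].total_length
    for t in tracks[1:]:
        if t.total_length != total:
            raise ValueError(
                f"track length mismatch on {t.chromosome}: "
                f"{t.total_length} != {total}"
            )
        if t.chromosome != tracks[0].chromosome:
            raise ValueError("tracks belong to different chromosomes")
    bounds = np.unique(np.concatenate([t.ends for t in tracks]))
    seg_starts = np.concatenate(([0], bounds[:-1]))
    lengths = bounds - seg_starts
    matrix = np.empty((len(tracks), bounds.size), dtype=float)
    for k, t in enumerate(tracks):
        idx = np.searchsorted(t.ends, seg_starts, side="right")
        matrix[k] = t.values[idx]
    return lengths, matrix


def merge_tracks(
    tracks: Sequence[RunLengthTrack],
    func: Callable[[np.ndarray], np.ndarray],
) -> RunLengthTrack:
    """Position-wise combination of equal-length tracks.

    ``func`` receives the aligned value matrix (tracks x segments) and must
    reduce over axis 0 (e.g. ``lambda m: m.mean(axis=0)``).  Runs never need
    decoding: the combination is computed once per aligned segment.
    """
    if not tracks:
        raise ValueError("no tracks to merge")
    lengths, matrix = _aligned_values(tracks)
    return RunLengthTrack(tracks[0].chromosome, func(matrix), lengths)


def segment_table(tracks: Sequence[RunLengthTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Aligned segment lengths and per-track values as a segments x tracks matrix.

    This is the "collapse the genome into constant stretches" primitive: each
    returned row is a maximal stretch of positions over which *every* input
    track is constant.
    """
    lengths, matrix = _aligned_values(tracks)
    return lengths, matrix.T
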