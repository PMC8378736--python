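"""Independent reference implementations used as test oracles.

These are deliberately naive (dense, brute-force, textbook-formula)
versions of the package's optimized algorithms; they share definitions but
no code with the implementations they check.
"""

from __future__ import annotations

import itertools
from math import log, log1p

import numpy as np


def dense_viterbi(obs: list[float], p) -> list[int]:
    """Position-by-position two-state Viterbi over dense observations.

    Same model and tie-breaking convention (prefer the not-diff state) as
    the package's sparse decoder, but with no run skipping.
    """
    t00, t01 = log1p(-p.tp1), log(p.tp1)
    t10, t11 = log(p.tp2), log1p(-p.tp2)
    e0 = (log(p.ep), log1p(-p.ep))
    e1 = (log1p(-p.ep), log(p.ep))
    bs = [1 if v < p.pt else 0 for v in obs]
    s0 = log1p(-p.start_prob_diff) + e0[bs[0]]
    s1 = log(p.start_prob_diff) + e1[bs[0]]
    bps: list[tuple[int, int]] = []
    for b in bs[1:]:
        pick0 = s0 + t00 >= s1 + t10
        pick1 = s0 + t01 >= s1 + t11
        n0 = (s0 + t00 if pick0 else s1 + t10) + e0[b]
        n1 = (s0 + t01 if pick1 else s1 + t11) + e1[b]
        bps.append((0 if pick0 else 1, 0 if pick1 else 1))
        s0, s1 = n0, n1
    st = 0 if s0 >= s1 else 1
    path = [st]
    for bp in reversed(bps):
        st = bp[st]
        path.append(st)
    return path[::-1]


def brute_force_viterbi(obs: list[float], p) -> list[int]:
    """Exhaustive enumeration of all 2^n state paths (n <= ~12)."""
    t = [[log1p(-p.tp1), log(p.tp1)], [log(p.tp2), log1p(-p.tp2)]]
    e0 = (log(p.ep), log1p(-p.ep))
    e1 = (log1p(-p.ep), log(p.ep))
    bs = [1 if v < p.pt else 0 for v in obs]
    best, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=len(obs)):
        sc = log1p(-p.start_prob_diff) if path[0] == 0 else log(p.start_prob_diff)
        sc += (e0 if path[0] == 0 else e1)[bs[0]]
        for i in range(1, len(obs)):
            sc += t[path[i - 1]][path[i]]
            sc += (e0 if path[i] == 0 else e1)[bs[i]]
        if sc > best:
            best, best_path = sc, path
    return list(best_path)


def expand_path(runs: list[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for state, n in runs:
        out.extend([state] * n)
    return out


def brute_force_ir(f: np.ndarray, t: float, signed_area: bool = False):
    """Enumerate all crossing-bounded intervals satisfying the MAAT predicate.

    ``f`` is a dense one-sign fold-change signal.  Returns the maximal valid
    intervals as 1-based closed (start, end) pairs, sorted.
    """
    n = len(f)
    above = [v >= t for v in f]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    if not runs:
        return []
    g = [(v - t) if signed_area else max(v - t, 0.0) for v in f]

    def maat(a: int, b: int) -> float:
        return sum(g[a - 1 : b]) / (b - a + 1)

    def valid(i: int, j: int) -> bool:
        a, b = runs[i][0], runs[j][1]
        for k in range(i, j):
            for q in (runs[k][1] + 1, runs[k + 1][0] - 1):
                if maat(a, q) < t or maat(q, b) < t:
                    return False
        return True

    m = len(runs)
    vals = [(i, j) for i in range(m) for j in range(i, m) if valid(i, j)]
    return sorted(
        (runs[i][0], runs[j][1])
        for (i, j) in vals
        if not any(ii <= i and j <= jj and (ii, jj) != (i, j) for (ii, jj) in vals)
    )


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up, computed directly from the sort."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj
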