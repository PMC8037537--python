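"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by a route independent of the
implementation it checks: exhaustive dynamic programs written from scratch,
explicit enumerations, or a second formulation of the same statistic.
"""

from __future__ import annotations

import itertools

import numpy as np

from cerna_weaver.sequences import PAIRABLE, revcomp

BASES = "ACGU"


def nw_score(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Needleman-Wunsch optimal global score (end gaps penalized)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = i * gap
    for j in range(1, m + 1):
        dp[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            dp[i][j] = max(dp[i - 1][j - 1] + s, dp[i - 1][j] + gap, dp[i][j - 1] + gap)
    return dp[n][m]


def sw_score(q: str, s: str, match: int = 2, mismatch: int = -3, gap: int = -5) -> int:
    """Smith-Waterman optimal local score, quadratic DP."""
    n, m = len(q), len(s)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def sw_scores_batch(Q: np.ndarray, S: np.ndarray, match=2, mismatch=-3, gap=-5) -> np.ndarray:
    """Max local score for each of many (query, subject) pairs at once.

    Q, S: integer-coded arrays of shape (n_pairs, len).  The DP runs over
    cells with all pairs vectorized.
    """
    npairs, n = Q.shape
    m = S.shape[1]
    best = np.zeros(npairs)
    prev = np.zeros((npairs, m + 1))
    for i in range(1, n + 1):
        cur = np.zeros((npairs, m + 1))
        qi = Q[:, i - 1]
        for j in range(1, m + 1):
            sub = np.where(qi == S[:, j - 1], match, mismatch)
            cur[:, j] = np.maximum.reduce(
                [np.zeros(npairs), prev[:, j - 1] + sub, prev[:, j] + gap, cur[:, j - 1] + gap]
            )
        best = np.maximum(best, cur.max(axis=1))
        prev = cur
    return best


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by explicit summation of hypergeometric point masses."""
    from math import comb

    total = comb(N, K)
    s = 0
    for x in range(k, min(K, n) + 1):
        s += comb(n, x) * comb(N - n, K - x)
    return s / total


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, second implementation."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return np.clip(q, 0.0, 1.0)


def tail_cost_enum(tail: str, rc_ext: str, max_bulge: int) -> float:
    """Minimum unit-cost alignment of tail vs rc_ext with a total gap budget.

    Recursive enumeration (memoized on the explicit gap budget); trailing
    rc_ext is free once the tail is consumed.
    """
    from functools import lru_cache

    m, n = len(tail), len(rc_ext)

    @lru_cache(maxsize=None)
    def go(i: int, j: int, gaps: int) -> float:
        if i == m:
            return 0.0
        best = float("inf")
        if j < n:
            best = go(i + 1, j + 1, gaps) + (0.0 if tail[i] == rc_ext[j] else 1.0)
        if gaps < max_bulge:
            if j < n:
                best = min(best, go(i, j + 1, gaps + 1) + 1.0)
            best = min(best, go(i + 1, j, gaps + 1) + 1.0)
        return best

    cost = go(0, 0, 0)
    if cost == float("inf"):
        cost = float(m)
    return min(cost / m, 1.0) if m else 0.0


def duplex_energy_enum(q: str, t: str, model) -> float:
    """Exhaustive minimum duplex energy over all co-linear pairings.

    Enumerates every monotone set of allowed base pairs between q and the
    reversed t, summing stack energies for strand-adjacent pairs and charging
    the bulge penalty for each interior gap event.
    """
    c = t[::-1]
    n, m = len(q), len(c)
    best = 0.0  # no pairing at all
    for k in range(1, min(n, m) + 1):
        for qpos in itertools.combinations(range(n), k):
            for tpos in itertools.combinations(range(m), k):
                pairs = [q[i] + c[j] for i, j in zip(qpos, tpos)]
                if any(p not in PAIRABLE for p in pairs):
                    continue
                e = 0.0
                for x in range(1, k):
                    gap_q = qpos[x] - qpos[x - 1] - 1
                    gap_t = tpos[x] - tpos[x - 1] - 1
                    u = gap_q + gap_t
                    if u == 0:
                        e += model.stack(pairs[x - 1], pairs[x])
                    else:
                        e += model.bulge_open + model.bulge_extend * (u - 1)
                best = min(best, e)
    return model.initiation + best


def count_occurrences(hay: str, needle: str) -> list[int]:
    """1-based start positions of all (overlapping) occurrences."""
    return [i + 1 for i in range(len(hay) - len(needle) + 1) if hay[i : i + len(needle)] == needle]


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def perfect_site_pairs(mirnas, transcripts) -> set[tuple[str, str, int]]:
    """Exhaustive (mirna, target, site_start) triples with exact seed complement."""
    out = set()
    for t in transcripts:
        lo, hi = t.searchable_region
        region = t.sequence[lo - 1 : hi]
        for m in mirnas:
            needle = revcomp(m.seed)
            for pos in count_occurrences(region, needle):
                out.add((m.id, t.id, lo + pos - 1))
    return out
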