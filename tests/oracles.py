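"""Naive reference implementations used as independent oracles.

Everything here is deliberately brute-force (double loops, full
enumeration) and shares no code with the package's vectorized paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def exact_rank_sum_two_sided(a, b) -> float:
    """Two-sided rank-sum p by complete enumeration of group assignments,
    defined as 2*min(tail) capped at 1."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    # average ranks by hand
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[:n_a])
    lo = hi = 0
    total = comb(n, n_a)
    for idx in combinations(range(n), n_a):
        w = sum(ranks[i] for i in idx)
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def naive_hodges_lehmann(a, b) -> float:
    diffs = sorted(x - y for x in a for y in b)
    k = len(diffs)
    mid = k // 2
    return diffs[mid] if k % 2 else (diffs[mid - 1] + diffs[mid]) / 2.0


def naive_quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Column-wise quantile normalization with average-tie handling,
    written as plain loops."""
    n, k = x.shape
    mean_sorted = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(k):
        col = x[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        assigned = [0.0] * n
        i = 0
        while i < n:
            run = [i]
            while run[-1] + 1 < n and col[order[run[-1] + 1]] == col[order[i]]:
                run.append(run[-1] + 1)
            val = float(np.mean([mean_sorted[r] for r in run]))
            for r in run:
                assigned[order[r]] = val
            i = run[-1] + 1
        out[:, j] = assigned
    return out


def naive_window_indices(chroms, centers, i, bandwidth) -> list[int]:
    """O(n) scan over every probe for probe i's window."""
    return [
        j
        for j in range(len(centers))
        if chroms[j] == chroms[i] and abs(int(centers[j]) - int(centers[i])) <= bandwidth
    ]


def naive_qvalues(p, pi0) -> np.ndarray:
    """Step-down monotonization, quadratic loop over sorted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos_i in range(m):
        candidates = [
            pi0 * m * p[order[pos_j]] / (pos_j + 1) for pos_j in range(pos_i, m)
        ]
        q[order[pos_i]] = min(1.0, min(candidates))
    return q


def interval_union_length(intervals) -> int:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def jaccard(a_start, a_end, b_start, b_end) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start))
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union if union else 0.0
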