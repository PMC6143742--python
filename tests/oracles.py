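"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately naive (enumeration or O(n^3) agglomeration) so
it shares no code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def mwu_exact_two_sided(x, y) -> tuple[float, float]:
    """Mann-Whitney U and exact two-sided p by full labeling enumeration.

    Enumerates all C(n_x + n_y, n_x) assignments of the pooled values to
    the first group; valid for tie-free data. p = min(1, 2 * min(P(U <= u),
    P(U >= u))) under the exact permutation null.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n_x = len(x)

    def u_stat(group_a, group_b):
        return sum(1 for a in group_a for b in group_b if a > b)

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n_x):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the support.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance for floating point).
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def naive_average_linkage(dist: np.ndarray, k: int):
    """O(n^3) average-linkage agglomeration from a dense distance matrix.

    Inter-cluster distance is the mean over all original pairwise
    distances; merges pick the global minimum (ties: lexicographically
    first pair). Returns (labels_at_k, merge_heights).
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    labels_at_k = None
    while len(clusters) > 1:
        if len(clusters) == k:
            labels_at_k = np.empty(n, dtype=int)
            for gi, members in enumerate(clusters):
                labels_at_k[members] = gi
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    if k == 1:
        labels_at_k = np.zeros(n, dtype=int)
    return labels_at_k, heights


def naive_cophenetic(dist: np.ndarray) -> np.ndarray:
    """Cophenetic distances from the naive average-linkage hierarchy."""
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph
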