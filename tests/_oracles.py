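"""Brute-force reference implementations used only as test oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(nm) dynamic-programming edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def agglomerative_oracle(dist: np.ndarray, linkage: str, cut: float) -> list[int]:
    """O(n^3) naive agglomerative clustering with inclusive cut.

    Repeatedly merges the closest cluster pair (complete or single linkage)
    while the merge distance is <= cut; ties broken by smallest cluster
    indices.  Returns a label per item (labels arbitrary but consistent).
    """
    n = len(dist)
    clusters: list[set[int]] = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pair_d = [dist[a][b] for a in clusters[i] for b in clusters[j]]
                d = max(pair_d) if linkage == "complete" else min(pair_d)
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        if d > cut + 1e-12:
            break
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    labels = [0] * n
    for lab, members in enumerate(clusters):
        for m in members:
            labels[m] = lab
    return labels


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by full enumeration of tables with the same
    margins, summing probabilities <= the observed table's (tolerance 1e-7)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # hypergeometric P(X = x) with margins fixed
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def rarefaction_enumeration(matrix: np.ndarray, t: int) -> float:
    """Mean richness over all size-t replicate subsets, by enumeration."""
    m = matrix.shape[1]
    vals = []
    for cols in itertools.combinations(range(m), t):
        sub = matrix[:, list(cols)]
        vals.append(int(sub.any(axis=1).sum()))
    return float(np.mean(vals))


def chao2_closed_form(matrix: np.ndarray) -> float:
    """Chao2 point estimate recomputed directly from a raw incidence matrix."""
    row_sums = matrix.sum(axis=1)
    s_obs = int((row_sums > 0).sum())
    q1 = int((row_sums == 1).sum())
    q2 = int((row_sums == 2).sum())
    m = matrix.shape[1]
    a = (m - 1) / m
    if q2 > 0:
        return s_obs + a * q1 * q1 / (2 * q2)
    return s_obs + a * q1 * (q1 - 1) / 2
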