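"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — enumeration, bitmaps, quadratic
agglomeration — kept separate from the package so each test compares two
unrelated computational routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enum(m1: int, n1: int, m2: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric tail enumeration.

    Sums P(X = x) over every x in the support of Hypergeom(N, k, n1) whose
    probability does not exceed that of the observed table (with the usual
    1 + 1e-7 relative slack for mathematically tied outcomes).
    """
    N, k = n1 + n2, m1 + m2
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, k, n1)
    p_obs = hypergeom.pmf(m1, N, k, n1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def bh_naive(pvalues) -> np.ndarray:
    """Benjamini–Hochberg by the definition: sort, scale, running minimum."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bitmap_union(intervals, length: int) -> np.ndarray:
    """Per-basepair boolean coverage of an interval list on one chromosome."""
    bm = np.zeros(length, dtype=bool)
    for iv in intervals:
        bm[iv.start: iv.end] = True
    return bm


def bitmap_to_regions(bm: np.ndarray):
    """Maximal runs of True as (start, end) pairs."""
    padded = np.concatenate([[False], bm, [False]])
    flips = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(flips[0::2], flips[1::2]))


def merge_bitmap(intervals, distance: int, length: int):
    """mergeBed -d semantics by basepair painting: paint each interval plus
    a `distance` halo, take maximal runs, then trim each run to the extent
    of the real intervals inside it."""
    halo = np.zeros(length + distance + 1, dtype=bool)
    for iv in intervals:
        halo[iv.start: min(iv.end + distance, len(halo))] = True
    real = bitmap_union(intervals, length)
    out = []
    for s, e in bitmap_to_regions(halo):
        inside = np.flatnonzero(real[s: min(e, length)])
        if len(inside):
            out.append((s + int(inside[0]), s + int(inside[-1]) + 1))
    return out


def overlap_bp_bitmap(query, features, length: int) -> int:
    return int((bitmap_union([query], length) & bitmap_union(features, length)).sum())


def loci_union_find(windows, merge_distance: int):
    """Connected components of windows under the gap <= distance relation."""
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = windows[i], windows[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= merge_distance:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def average_linkage_naive(D: np.ndarray) -> np.ndarray:
    """O(n^3) average-linkage agglomeration on a full distance matrix.

    Returns the cophenetic distance matrix: entry (i, j) is the height at
    which observations i and j first share a cluster.
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        new_dist = {
            key: d for key, d in dist.items()
            if a not in key and b not in key
        }
        for c in clusters:
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            new_dist[(min(c, next_id), max(c, next_id))] = (na * da + nb * db) / (na + nb)
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return coph
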