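"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity by direct enumeration or a naive
algorithm, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg by the step-up formula:
    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out


def hypergeom_upper_tail(k, M, n, N):
    """P(X >= k) for X ~ Hypergeom(M, n, N) by direct summation."""
    total = comb(M, N)
    return sum(comb(n, x) * comb(M - n, N - x)
               for x in range(max(k, N - (M - n)), min(n, N) + 1)) / total


def fisher_exact_enum(table):
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing point probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = point_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(point_prob(x) for x in range(lo, hi + 1)
               if point_prob(x) <= p_obs * (1 + 1e-9))


def complete_linkage_heights(points):
    """Merge heights of naive O(n^3) complete-linkage clustering."""
    clusters = [[i] for i in range(len(points))]
    pts = np.asarray(points, dtype=float)
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(np.linalg.norm(pts[a] - pts[b])
                    for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def flood_fill_components(nodes, edges):
    """Connected components by explicit BFS flood fill."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen, comps = set(), []
    for start in sorted(adj):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(tuple(sorted(comp)))
    return comps


def per_base_consensus(replicate_intervals, chrom_len, min_support=2):
    """Consensus peak spans by per-base accounting on one toy chromosome.

    A base is supported when peaks from >= min_support distinct replicates
    cover it; retained spans are the maximal merged spans of overlapping
    peaks (any replicate) that contain at least one supported base.
    """
    cover = np.zeros((len(replicate_intervals), chrom_len), dtype=bool)
    union = np.zeros(chrom_len, dtype=bool)
    for r, ivs in enumerate(replicate_intervals):
        for s, e in ivs:
            cover[r, s:e] = True
            union[s:e] = True
    supported = cover.sum(axis=0) >= min_support
    spans = []
    i = 0
    while i < chrom_len:
        if union[i]:
            j = i
            while j < chrom_len and union[j]:
                j += 1
            if supported[i:j].any():
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans
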