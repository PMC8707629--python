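"""Independent brute-force oracles used to check the statistical core.

Everything here is deliberately naive and self-contained: average ranks
computed by sorting, Pearson from the definition, Kendall tau-b by pair
counting, the exact Mann-Whitney null by full enumeration of group
assignments, step-up FDR by hand, Ward agglomeration by recomputing
cluster centroids at every step, and interval containment by a double
loop.  None of it calls the package or scipy.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np


def average_ranks(x):
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        r = (i + j) / 2 + 1  # average of 1-based positions i..j
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman(x, y):
    return pearson(average_ranks(x), average_ranks(y))


def kendall_tau_b(x, y):
    n = len(x)
    concordant = discordant = 0
    for i, j in combinations(range(n), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        if s > 0:
            concordant += 1
        elif s < 0:
            discordant += 1
    n0 = n * (n - 1) // 2

    def tie_term(v):
        seen = {}
        for a in v:
            seen[a] = seen.get(a, 0) + 1
        return sum(t * (t - 1) // 2 for t in seen.values())

    denom = sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (concordant - discordant) / denom


def mwu_exact_p(x0, x1):
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Assumes tie-free pooled data.  U counts pairs where a group-1 value
    exceeds a group-0 value; the null distribution is symmetric, so the
    two-sided p sums both tails at the observed separation.
    """
    pooled = list(x0) + list(x1)
    n0, n1 = len(x0), len(x1)

    def u_stat(group1_idx):
        g1 = set(group1_idx)
        u = 0
        for i in range(len(pooled)):
            for j in range(len(pooled)):
                if i in g1 and j not in g1 and pooled[i] > pooled[j]:
                    u += 1
        return u

    u_obs = u_stat(range(n0, n0 + n1))
    hi = max(u_obs, n0 * n1 - u_obs)
    lo = n0 * n1 - hi
    count = 0
    for idx in combinations(range(n0 + n1), n1):
        u = u_stat(idx)
        if u >= hi or u <= lo:
            count += 1
    return count / comb(n0 + n1, n1)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted values by the step-up formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def ward_merges(points):
    """Naive ward.D2 agglomeration recomputing centroids each step.

    Returns a list of (frozenset of leaf indices in the merged cluster,
    height) with height = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A -
    centroid_B||, which matches heights of ward linkage on Euclidean
    distances.  Ties broken by the smallest index pair.
    """
    points = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = points[clusters[a]].mean(axis=0)
                cb = points[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                h = sqrt(2.0 * na * nb / (na + nb)) * float(np.linalg.norm(ca - cb))
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merged = clusters[a] + clusters[b]
        merges.append((frozenset(merged), h))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def assign_by_scan(variants, regions):
    """gene_id -> sorted variant indices by double-loop containment.

    ``variants``: list of (chrom, pos); ``regions``: list of
    (gene_id, chrom, region_start, region_end) half-open.
    """
    out = {g: [] for g, *_ in regions}
    for i, (chrom, pos) in enumerate(variants):
        for gene_id, rchrom, start, end in regions:
            if chrom == rchrom and start <= pos < end:
                out[gene_id].append(i)
    return out
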