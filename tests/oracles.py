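"""Independent definitional implementations used as test oracles.

Deliberately naive: explicit double loops and exhaustive enumeration,
sharing no code with the package paths they check.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b)
               if x in "ACGT" and y in "ACGT" and x != y)


def brute_amova(seqs, pops, groups):
    """Three-level variance components from first principles: explicit
    pair loops for every sum of squares, textbook method-of-moments
    coefficients. *groups* is a list of lists of population ids."""
    n = len(seqs)
    d2 = [[hamming(seqs[i], seqs[j]) for j in range(n)] for i in range(n)]
    pop_ids = sorted(set(pops))
    P, G = len(pop_ids), len(groups)
    group_of = {p: gi for gi, grp in enumerate(groups) for p in grp}

    def ss(indices):
        return sum(d2[i][j] for i, j in itertools.combinations(indices, 2)) / len(indices)

    everyone = list(range(n))
    ss_total = ss(everyone)
    ss_wp = sum(ss([i for i in everyone if pops[i] == p]) for p in pop_ids)
    ss_wg = sum(ss([i for i in everyone if group_of[pops[i]] == gi])
                for gi in range(G))
    n_p = {p: sum(1 for x in pops if x == p) for p in pop_ids}
    n_g = [sum(n_p[p] for p in grp) for grp in groups]

    sigma_c = ss_wp / (n - P)
    if G == 1:
        nc = (n - sum(v * v for v in n_p.values()) / n) / (P - 1)
        sigma_b = ((ss_wg - ss_wp) / (P - 1) - sigma_c) / nc
        return None, sigma_b, sigma_c
    sum_np2_over_ng = sum(sum(n_p[p] ** 2 for p in grp) / ng
                          for grp, ng in zip(groups, n_g))
    n1 = (n - sum_np2_over_ng) / (P - G)
    sigma_b = ((ss_wg - ss_wp) / (P - G) - sigma_c) / n1
    n2 = (sum_np2_over_ng - sum(v * v for v in n_p.values()) / n) / (G - 1)
    n3 = (n - sum(v * v for v in n_g) / n) / (G - 1)
    sigma_a = ((ss_total - ss_wg) / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def bh_bruteforce(pvals):
    """Adjusted p as the smallest FDR level at which each hypothesis is
    rejected by the literal step-up rule, found by scanning a fine grid of
    candidate levels (the set of m*p_i/rank values)."""
    p = list(pvals)
    m = len(p)
    candidates = sorted({pi * m / r for pi in p for r in range(1, m + 1)} | {1.0})

    def rejected_at(q):
        srt = sorted(p)
        kmax = 0
        for k, pk in enumerate(srt, start=1):
            if pk <= q * k / m + 1e-12:
                kmax = k
        return set() if kmax == 0 else {i for i, pi in enumerate(p) if pi <= srt[kmax - 1]}

    out = []
    for i in range(m):
        level = next(q for q in candidates if i in rejected_at(q))
        out.append(min(level, 1.0))
    return out


def all_spanning_trees(n):
    """Every labelled spanning tree of K_n via Prufer sequences."""
    if n == 1:
        return [[]]
    if n == 2:
        return [[(0, 1)]]
    trees = []
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for s in seq:
            degree[s] += 1
        leaves = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(leaves)
        edges = []
        for v in seq:
            leaf = heapq.heappop(leaves)
            edges.append((min(leaf, v), max(leaf, v)))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, v)
        u, v = heapq.heappop(leaves), heapq.heappop(leaves)
        edges.append((min(u, v), max(u, v)))
        trees.append(edges)
    return trees


def union_of_msts(weight: np.ndarray) -> set[tuple[int, int]]:
    """Exhaustive union of all minimum-total-weight spanning trees."""
    n = weight.shape[0]
    trees = all_spanning_trees(n)
    totals = [sum(weight[e] for e in t) for t in trees]
    best = min(totals)
    out: set[tuple[int, int]] = set()
    for t, tot in zip(trees, totals):
        if tot == best:
            out.update(t)
    return out
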