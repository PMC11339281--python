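"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a statistic from its definition by direct enumeration
or a triple loop, sharing no code with the library implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def es_brute_force(metric: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> float:
    """Weighted KS-like enrichment score by explicit walk over the ranking.

    ``metric`` is already in ranked (descending) order; ``hit`` marks set
    membership per position.
    """
    metric = np.asarray(metric, dtype=float)
    hit = np.asarray(hit, dtype=bool)
    n = len(metric)
    n_hit = int(hit.sum())
    n_miss = n - n_hit
    n_r = sum(abs(metric[i]) ** weight for i in range(n) if hit[i])
    run = 0.0
    best = 0.0
    for i in range(n):
        if hit[i]:
            run += (abs(metric[i]) ** weight / n_r) if n_r > 0 else 1.0 / n_hit
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def tom_brute_force(x: np.ndarray, beta: float = 6.0) -> np.ndarray:
    """Topological overlap by triple loop from the definition."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    a = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                a[i, j] = 1.0
            else:
                c = np.corrcoef(x[i], x[j])[0, 1]
                a[i, j] = abs(c) ** beta
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    t = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            s = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (s + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def mst_weight_brute_force(dist: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive search over all spanning
    trees (edge subsets of size n-1 that connect the graph)."""
    n = dist.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        ok = True
        w = 0.0
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
            w += dist[i, j]
        if ok and w < best:
            best = w
    return best


def hypergeom_upper_tail(k: int, set_size: int, universe: int, list_size: int) -> float:
    """P(X >= k) for the ORA overlap by explicit combinatorial sum."""
    from math import comb

    total = comb(universe, list_size)
    p = 0.0
    for x in range(k, min(set_size, list_size) + 1):
        p += comb(set_size, x) * comb(universe - set_size, list_size - x) / total
    return p


def wilcoxon_exact_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by enumeration of all label assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = _midranks(pooled)
    obs = ranks[:n].sum()
    stats = []
    for idx in itertools.combinations(range(n + m), n):
        stats.append(ranks[list(idx)].sum())
    stats = np.asarray(stats)
    mu = stats.mean()
    p = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)
    return float(p)


def _midranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def enumerate_splits_es(
    values: np.ndarray, genes: np.ndarray, members: set, k: int, weight: float = 1.0
):
    """All cluster-vs-rest splits of size k with their brute-force ES, using
    the epsilon-regularized log2 fold-change ranking (ties by gene name)."""
    values = np.asarray(values, dtype=float)  # genes x cells, un-logged means
    n = values.shape[1]
    out = []
    eps = 1e-9
    for idx in itertools.combinations(range(n), k):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        mi = values[:, mask].mean(axis=1)
        mo = values[:, ~mask].mean(axis=1)
        lfc = np.log2((mi + eps) / (mo + eps))
        order = np.lexsort((genes.astype(str), -lfc))
        hit = np.array([genes[i] in members for i in order])
        out.append(es_brute_force(lfc[order], hit, weight))
    return np.asarray(out)
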