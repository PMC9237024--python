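"""Independent brute-force oracles used to check the implementation.

These are deliberately naive (loops, textbook formulas, exhaustive
enumeration) and share no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_ward_d(dist: np.ndarray):
    """O(n^3) agglomeration with the Lance-Williams Ward update applied to
    the unsquared input distances (the classic ward.D recurrence).

    Returns (merges, heights): at each step the two frozensets of original
    indices merged, and the dissimilarity at which they merged. Ties are
    broken by the lowest (i, j) pair index.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = dist[i, j]
    merges, heights = [], []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(D.items(), key=lambda kv: (kv[1], kv[0]))[0]
        i, j = best
        h = D[(i, j)]
        merges.append((clusters[i], clusters[j]))
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        newD = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            dij = D[(i, j)]
            newD[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        clusters[next_id] = clusters[i] | clusters[j]
        sizes[next_id] = ni + nj
        active = [k for k in active if k not in (i, j)] + [next_id]
        D = {
            (a, b): v
            for (a, b), v in D.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in newD.items():
            D[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return merges, heights


def linkage_merge_sets(Z: np.ndarray, n: int):
    """Merge sequence of a scipy linkage matrix as pairs of original-index sets."""
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        merges.append((clusters[a], clusters[b]))
        clusters[n + step] = clusters[a] | clusters[b]
    return merges


def spearman_rho_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (average ties) then Pearson, with explicit loops for the ranks."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def silhouette_brute(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Textbook per-point silhouette from a distance matrix; singletons 0."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([dist[i, j] for j in own])
        b = np.inf
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, np.mean([dist[i, j] for j in other]))
        s[i] = (b - a) / max(a, b)
    return s


def gsea_es_brute(values_sorted_desc: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted KS running sum computed with an explicit loop (weight 1)."""
    N = len(values_sorted_desc)
    nh = int(np.sum(in_set))
    hit_total = float(np.sum(np.abs(values_sorted_desc[in_set])))
    running = 0.0
    best = 0.0
    for i in range(N):
        if in_set[i]:
            running += abs(values_sorted_desc[i]) / hit_total
        else:
            running -= 1.0 / (N - nh)
        if abs(running) > abs(best):
            best = running
    return best


def gsea_exact_null(values_sorted_desc: np.ndarray, set_size: int) -> np.ndarray:
    """ES over every same-size subset of positions (exact permutation null)."""
    N = len(values_sorted_desc)
    out = []
    for combo in itertools.combinations(range(N), set_size):
        mask = np.zeros(N, dtype=bool)
        mask[list(combo)] = True
        out.append(gsea_es_brute(values_sorted_desc, mask))
    return np.array(out)


def bh_stepup_brute(p: np.ndarray) -> np.ndarray:
    """Step-up BH from the definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, m * p[idx] / rank_from_top)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)
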