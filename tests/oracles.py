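"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive — dense matrices, O(n³) triple
enumeration, exhaustive set-partition search, boolean transitive closure —
and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def adjacency(g: nx.Graph, order: list, weighted: bool = True) -> np.ndarray:
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    A = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1)) if weighted else 1.0
        A[idx[u], idx[v]] += w
        A[idx[v], idx[u]] += w
    return A


def modularity_double_sum(g: nx.Graph, membership: dict, weighted: bool = True) -> float:
    """Q = (1/2m) ΣΣ (A_ij − k_i k_j / 2m) δ(c_i, c_j), dense evaluation."""
    order = list(g.nodes)
    A = adjacency(g, order, weighted)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    labels = np.array([membership[v] for v in order])
    delta = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_m) * delta).sum() / two_m)


def barrat_triples(g: nx.Graph) -> dict:
    """Barrat local clustering by direct enumeration of ordered triples.

    c_i = [1/(s_i(k_i−1))] Σ_{j,h} [(w_ij + w_ih)/2] a_ij a_ih a_jh over all
    ordered pairs (j, h), j ≠ h.  None when degree < 2.
    """
    order = list(g.nodes)
    A = adjacency(g, order, weighted=True)
    B = (A > 0).astype(float)
    out = {}
    n = len(order)
    for i in range(n):
        k = int(B[i].sum())
        s = A[i].sum()
        if k < 2:
            out[order[i]] = None
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == h:
                    continue
                acc += (A[i, j] + A[i, h]) / 2.0 * B[i, j] * B[i, h] * B[j, h]
        out[order[i]] = acc / (s * (k - 1))
    return out


def set_partitions(items: list):
    """All set partitions, generated by restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    a = [0] * n
    b = [0] * n  # b[i] = max(a[0..i-1])
    while True:
        groups: dict[int, list] = {}
        for x, c in zip(items, a):
            groups.setdefault(c, []).append(x)
        yield list(groups.values())
        i = n - 1
        while i > 0 and a[i] == b[i] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            b[j] = max(b[j - 1], a[j - 1])
            a[j] = 0


def best_partition_Q(g: nx.Graph, weighted: bool = True) -> float:
    """Exhaustive-search maximal modularity (vectorised double-sum form)."""
    order = list(g.nodes)
    A = adjacency(g, order, weighted)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    M = A - np.outer(k, k) / two_m
    best = -np.inf
    for part in set_partitions(order):
        labels = {}
        for c, grp in enumerate(part):
            for v in grp:
                labels[v] = c
        lab = np.array([labels[v] for v in order])
        delta = lab[:, None] == lab[None, :]
        q = (M * delta).sum() / two_m
        best = max(best, q)
    return float(best)


def reachability_components(g: nx.Graph) -> list[frozenset]:
    """Connected components via boolean transitive closure."""
    order = list(g.nodes)
    n = len(order)
    R = (adjacency(g, order) > 0) | np.eye(n, dtype=bool)
    for _ in range(n):
        R = R | (R @ R)
    comps = set()
    for i in range(n):
        comps.add(frozenset(order[j] for j in range(n) if R[i, j]))
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5, wmax: int = 4) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j, weight=int(rng.integers(1, wmax + 1)))
    return g
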