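"""Modularity and community detection on weighted similarity graphs.

Four classic algorithms are implemented from their published definitions:

* **fastgreedy** — Clauset–Newman–Moore greedy agglomeration: start from
  singletons, repeatedly merge the community pair with the largest
  modularity gain, and return the dendrogram cut with maximal Q.
* **louvain** — Blondel et al. two-phase heuristic: local vertex moves
  maximising the modularity gain, then aggregation of communities into
  super-vertices, iterated until no improvement.
* **label_propagation** — Raghavan et al. asynchronous majority voting:
  unique initial labels, seeded-random sweep order, each vertex adopts the
  (weight-summed) majority label of its neighbourhood.
* **walktrap** — Pons–Latapy random-walk agglomeration: t-step transition
  probabilities define a vertex distance, adjacent communities are merged
  Ward-style by minimal variance increase, and the dendrogram is cut at
  maximal modularity.

Modularity follows the community-sum form

    Q = sum_i (e_ii - a_i^2)

with ``e_ii`` the fraction of edge weight inside community ``i`` and
``a_i`` the fraction of edge ends attached to it.  All algorithms accept a
``weighted`` flag; with ``weighted=False`` every edge counts 1, which on a
unit-weight graph coincides with the weighted result.

Determinism: fastgreedy breaks equal-gain merges by the smallest community
id pair; louvain visits vertices in seeded shuffled order; label
propagation breaks ties uniformly from the tied set with the same seeded
RNG; walktrap is deterministic.  Isolated vertices always end up as
singleton communities under every algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Mapping

import networkx as nx
import numpy as np

from .metrics import density as _density

__all__ = [
    "Partition",
    "modularity",
    "fastgreedy",
    "louvain",
    "label_propagation",
    "walktrap",
    "detect_all",
    "SummaryRow",
]

_LOUVAIN_TOL = 1e-12  # a full pass must improve Q by at least this to continue


@dataclass
class Partition:
    """Vertex → community assignment with its modularity on the source graph."""

    membership: dict[Hashable, int]
    n_communities: int
    Q: float
    method: str = ""

    def communities(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_communities)]
        for v, c in self.membership.items():
            out[c].add(v)
        return out

    def labels(self, order: list[Hashable]) -> list[int]:
        return [self.membership[v] for v in order]


def _canonical(nodes: list[Hashable], comm: Mapping[Hashable, int]) -> dict[Hashable, int]:
    """Relabel communities to 0..c-1 in order of first appearance over ``nodes``."""
    remap: dict[int, int] = {}
    out: dict[Hashable, int] = {}
    for v in nodes:
        c = comm[v]
        if c not in remap:
            remap[c] = len(remap)
        out[v] = remap[c]
    return out


def _edge_weight(data: dict, weighted: bool) -> float:
    return float(data.get("weight", 1)) if weighted else 1.0


def modularity(g: nx.Graph, membership: Mapping[Hashable, int], *, weighted: bool = True) -> float:
    """Modularity Q = Σ_i (e_ii − a_i²) of a partition.

    ``e_ii`` is the within-community fraction of total edge weight (edge
    count when ``weighted=False``) and ``a_i`` the fraction of edge ends in
    community ``i``.  An edgeless graph has Q = 0 by convention.

    Raises
    ------
    KeyError
        If a graph vertex is missing from ``membership``.
    ValueError
        If ``membership`` names vertices absent from the graph.
    """
    for v in g.nodes:
        if v not in membership:
            raise KeyError(f"vertex {v!r} missing from membership")
    extra = set(membership) - set(g.nodes)
    if extra:
        raise ValueError(f"membership names unknown vertex {sorted(map(str, extra))[0]!r}")
    m = sum(_edge_weight(d, weighted) for _, _, d in g.edges(data=True))
    if m == 0:
        return 0.0
    internal: dict[int, float] = {}
    ends: dict[int, float] = {}
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        cu, cv = membership[u], membership[v]
        ends[cu] = ends.get(cu, 0.0) + w
        ends[cv] = ends.get(cv, 0.0) + w
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
    q = 0.0
    for c, a in ends.items():
        q += internal.get(c, 0.0) / m - (a / (2.0 * m)) ** 2
    return q


def _make_partition(
    g: nx.Graph, comm: Mapping[Hashable, int], method: str, weighted: bool
) -> Partition:
    nodes = list(g.nodes)
    canon = _canonical(nodes, comm)
    c = max(canon.values(), default=-1) + 1
    return Partition(canon, c, modularity(g, canon, weighted=weighted), method)


# ---------------------------------------------------------------------------
# Fast greedy (Clauset–Newman–Moore)
# ---------------------------------------------------------------------------

def fastgreedy(g: nx.Graph, *, weighted: bool = True) -> Partition:
    """CNM greedy modularity agglomeration, best dendrogram cut returned.

    Merging communities i and j changes Q by ``w_ij/m − 2 a_i a_j`` where
    ``w_ij`` is the weight between them; the pair with maximal gain is merged
    (ties: lexicographically smallest id pair), the full merge sequence is
    recorded, and the prefix with maximal Q wins.  Isolated vertices are
    never merged and remain singletons.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = sum(_edge_weight(d, weighted) for _, _, d in g.edges(data=True))
    if m == 0:
        return Partition({v: i for i, v in enumerate(nodes)}, n, 0.0, "fastgreedy")

    between: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    a = [0.0] * n
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        i, j = idx[u], idx[v]
        between[i][j] = between[i].get(j, 0.0) + w
        between[j][i] = between[j].get(i, 0.0) + w
        a[i] += w / (2.0 * m)
        a[j] += w / (2.0 * m)

    q = -sum(x * x for x in a)  # singleton partition
    merges: list[tuple[int, int]] = []
    q_trace = [q]
    alive = set(range(n))
    while True:
        best: tuple[float, int, int] | None = None
        for i in alive:
            for j, w in between[i].items():
                if j <= i:
                    continue
                dq = w / m - 2.0 * a[i] * a[j]
                if best is None or dq > best[0] + 1e-15 or (
                    abs(dq - best[0]) <= 1e-15 and (i, j) < (best[1], best[2])
                ):
                    best = (dq, i, j)
        if best is None:
            break
        dq, i, j = best
        # merge j into i (i < j)
        q += dq
        merges.append((i, j))
        q_trace.append(q)
        a[i] += a[j]
        a[j] = 0.0
        for k, w in between[j].items():
            if k == i:
                continue
            between[i][k] = between[i].get(k, 0.0) + w
            between[k][i] = between[k].get(i, 0.0) + w
            del between[k][j]
        between[i].pop(j, None)
        between[j] = {}
        alive.discard(j)

    cut = int(np.argmax(q_trace))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in merges[:cut]:
        parent[find(j)] = find(i)
    comm = {v: find(idx[v]) for v in nodes}
    return _make_partition(g, comm, "fastgreedy", weighted)


# ---------------------------------------------------------------------------
# Louvain (Blondel et al.)
# ---------------------------------------------------------------------------

def _louvain_level(
    adj: list[dict[int, float]], rng: np.random.Generator
) -> tuple[list[int], float]:
    """One Louvain level: local moves until a full pass gains < tolerance.

    ``adj`` holds the (possibly aggregated) graph with self-loop weight
    stored at ``adj[v][v]``, counted once.  Returns the community of each
    vertex and the total modularity gain of the level.
    """
    n = len(adj)
    k = [sum(w for u, w in adj[v].items() if u != v) + 2.0 * adj[v].get(v, 0.0)
         for v in range(n)]
    two_m = sum(k)
    if two_m == 0:
        return list(range(n)), 0.0
    m = two_m / 2.0
    comm = list(range(n))
    sigma_tot = k.copy()
    total_gain = 0.0
    while True:
        pass_gain = 0.0
        order = rng.permutation(n)
        for v in order:
            cv = comm[v]
            kv = k[v]
            # weights from v to each neighbouring community (self-loop excluded)
            to_comm: dict[int, float] = {}
            for u, w in adj[v].items():
                if u == v:
                    continue
                to_comm[comm[u]] = to_comm.get(comm[u], 0.0) + w
            sigma_tot[cv] -= kv
            base = to_comm.get(cv, 0.0) / m - kv * sigma_tot[cv] / (2.0 * m * m)
            best_c, best_gain = cv, base
            for c in sorted(to_comm):
                if c == cv:
                    continue
                gain = to_comm[c] / m - kv * sigma_tot[c] / (2.0 * m * m)
                if gain > best_gain + 1e-15:
                    best_c, best_gain = c, gain
                elif abs(gain - best_gain) <= 1e-15 and c < best_c:
                    best_c = c
            sigma_tot[best_c] += kv
            comm[v] = best_c
            if best_c != cv:
                pass_gain += best_gain - base
        total_gain += pass_gain
        if pass_gain < _LOUVAIN_TOL:
            break
    return comm, total_gain


def louvain(g: nx.Graph, seed: int = 0, *, weighted: bool = True) -> Partition:
    """Louvain modularity optimisation (local moves + aggregation phases).

    Identical seed and graph give identical output; the returned Q never
    falls below the singleton partition's.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        i, j = idx[u], idx[v]
        adj[i][j] = adj[i].get(j, 0.0) + w
        if i != j:
            adj[j][i] = adj[j].get(i, 0.0) + w

    membership = list(range(n))
    while True:
        comm, gain = _louvain_level(adj, rng)
        labels = sorted(set(comm))
        remap = {c: i for i, c in enumerate(labels)}
        comm = [remap[c] for c in comm]
        membership = [comm[c] for c in membership]
        n_new = len(labels)
        if n_new == len(adj) and gain < _LOUVAIN_TOL:
            break
        # aggregate communities into super-vertices
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        for v, nbrs in enumerate(adj):
            cv = comm[v]
            for u, w in nbrs.items():
                cu = comm[u]
                if u == v:
                    new_adj[cv][cv] = new_adj[cv].get(cv, 0.0) + w
                elif u > v:
                    if cu == cv:
                        new_adj[cv][cv] = new_adj[cv].get(cv, 0.0) + w
                    else:
                        new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
                        new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
        if n_new == len(adj):
            break
        adj = new_adj

    return _make_partition(g, {v: membership[idx[v]] for v in nodes}, "louvain", weighted)


# ---------------------------------------------------------------------------
# Label propagation (Raghavan et al.)
# ---------------------------------------------------------------------------

def label_propagation(
    g: nx.Graph, seed: int = 0, *, weighted: bool = True, max_sweeps: int = 1000
) -> Partition:
    """Asynchronous majority-vote label propagation.

    Every vertex starts with a unique label; sweeps visit vertices in a
    freshly shuffled seeded order and each vertex adopts the label with the
    largest summed edge weight in its neighbourhood, ties broken uniformly
    at random among the tied labels.  Iteration stops when every vertex's
    label is already among its neighbourhood majorities.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    label = list(range(n))
    nbrs = [
        [(idx[u], _edge_weight(d, weighted)) for u, d in g.adj[v].items()]
        for v in nodes
    ]

    def majority_labels(i: int) -> list[int]:
        tally: dict[int, float] = {}
        for j, w in nbrs[i]:
            tally[label[j]] = tally.get(label[j], 0.0) + w
        if not tally:
            return [label[i]]
        top = max(tally.values())
        return [l for l, t in tally.items() if t >= top - 1e-12]

    for _ in range(max_sweeps):
        if all(label[i] in majority_labels(i) for i in range(n)):
            break
        for i in rng.permutation(n):
            cands = majority_labels(i)
            label[i] = int(cands[rng.integers(len(cands))]) if len(cands) > 1 else cands[0]

    return _make_partition(g, {v: label[idx[v]] for v in nodes}, "label_propagation", weighted)


# ---------------------------------------------------------------------------
# Walktrap (Pons–Latapy)
# ---------------------------------------------------------------------------

def walktrap(g: nx.Graph, t: int = 4, *, weighted: bool = True) -> Partition:
    """Random-walk agglomerative community detection.

    The t-step transition probabilities P^t give each vertex a profile;
    the distance between vertices (and communities, via member-averaged
    profiles) is the degree-weighted Euclidean distance between profiles.
    Adjacent communities are merged in order of minimal Ward variance
    increase ``Δσ = |C1||C2|/(|C1|+|C2|) · r²(C1,C2) / n`` and the merge
    sequence is cut where modularity peaks.  Isolated vertices stay
    singletons; connected components never mix (only adjacent communities
    merge).
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    if n == 0:
        return Partition({}, 0, 0.0, "walktrap")
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        W[idx[u], idx[v]] += w
        W[idx[v], idx[u]] += w
    deg = W.sum(axis=1)
    active = deg > 0
    P = np.eye(n)
    P[active] = W[active] / deg[active, None]
    Pt = np.linalg.matrix_power(P, t)
    inv_d = np.zeros(n)
    inv_d[active] = 1.0 / deg[active]

    # community state: profile (member-mean of Pt rows), size, neighbours
    profile: dict[int, np.ndarray] = {i: Pt[i].copy() for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    members_alive = set(range(n))
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in g.edges():
        i, j = idx[u], idx[v]
        if i != j:
            neigh[i].add(j)
            neigh[j].add(i)

    def dsigma(i: int, j: int) -> float:
        diff = profile[i] - profile[j]
        r2 = float(np.sum(diff * diff * inv_d))
        return size[i] * size[j] / (size[i] + size[j]) * r2 / n

    pairs: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in neigh[i]:
            if i < j:
                pairs[(i, j)] = dsigma(i, j)

    comm = list(range(n))
    snapshots: list[list[int]] = [comm.copy()]
    while pairs:
        (i, j), _ = min(pairs.items(), key=lambda kv: (kv[1], kv[0]))
        # merge j into i
        profile[i] = (size[i] * profile[i] + size[j] * profile[j]) / (size[i] + size[j])
        size[i] += size[j]
        neigh[i] |= neigh[j]
        neigh[i].discard(i)
        neigh[i].discard(j)
        for k in neigh[j]:
            neigh[k].discard(j)
            if k != i:
                neigh[k].add(i)
        for k in list(neigh[j]):
            pairs.pop((min(j, k), max(j, k)), None)
        for k in list(neigh[i]) + [j]:
            pairs.pop((min(j, k), max(j, k)), None)
            pairs.pop((min(i, k), max(i, k)), None)
        members_alive.discard(j)
        del profile[j], neigh[j], size[j]
        for k in neigh[i]:
            pairs[(min(i, k), max(i, k))] = dsigma(i, k)
        comm = [i if c == j else c for c in comm]
        snapshots.append(comm.copy())

    best = max(
        range(len(snapshots)),
        key=lambda s: modularity(
            g, {v: snapshots[s][idx[v]] for v in nodes}, weighted=weighted
        ),
    )
    return _make_partition(
        g, {v: snapshots[best][idx[v]] for v in nodes}, "walktrap", weighted
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SummaryRow:
    """One row of the algorithm×graph summary table.

    Columns mirror the standard reporting layout: community counts per
    algorithm, the weight threshold applied (if any), edge and vertex
    counts, connectedness and density.
    """

    fg: int
    wt: int
    bl: int
    lp: int
    weight_threshold: int | None
    E: int
    N: int
    is_connected: bool
    density: float | None

    def as_dict(self) -> dict:
        return {
            "FG": self.fg,
            "WT": self.wt,
            "BL": self.bl,
            "LP": self.lp,
            "Weight": self.weight_threshold,
            "E": self.E,
            "N": self.N,
            "Is.connected": self.is_connected,
            "Density": self.density,
        }


_ALGORITHMS: dict[str, str] = {
    "fg": "fastgreedy",
    "wt": "walktrap",
    "bl": "louvain",
    "lp": "label_propagation",
}


def detect_all(
    g: nx.Graph,
    seed: int = 0,
    *,
    weighted: bool = True,
    weight_threshold: int | None = None,
) -> tuple[dict[str, Partition], SummaryRow]:
    """Run all four algorithms and assemble the summary row."""
    parts = {
        "fg": fastgreedy(g, weighted=weighted),
        "wt": walktrap(g, weighted=weighted),
        "bl": louvain(g, seed, weighted=weighted),
        "lp": label_propagation(g, seed + 1, weighted=weighted),
    }
    N, E = g.number_of_nodes(), g.number_of_edges()
    row = SummaryRow(
        fg=parts["fg"].n_communities,
        wt=parts["wt"].n_communities,
        bl=parts["bl"].n_communities,
        lp=parts["lp"].n_communities,
        weight_threshold=weight_threshold,
        E=E,
        N=N,
        is_connected=(N > 0 and nx.is_connected(g)),
        density=_density(N, E) if N >= 2 else None,
    )
    return parts, row
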