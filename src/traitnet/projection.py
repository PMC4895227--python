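"""One-mode projections of the bipartite species×trait graph, and pruning.

A binary incidence ``A`` (species × traits) yields two weighted one-mode
graphs: the species graph ``P = A·Aᵀ`` (edge weight = number of traits a
species pair shares) and the feature graph ``F = Aᵀ·A`` (edge weight =
number of species a trait pair shares).  Diagonals are discarded; vertices
with no edges are kept, so the species graph order always equals the number
of species.

Graphs are plain :class:`networkx.Graph` objects with integer ``weight``
edge attributes; species vertices carry a ``family`` attribute and a
``kind`` attribute distinguishes species from feature graphs.  Weights are
raw co-occurrence counts, never normalized.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .trait_data import TraitMatrix

__all__ = [
    "project_species",
    "project_features",
    "filter_by_weight",
    "connected_components",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

# above this order the A·Aᵀ product goes through scipy.sparse; results identical
_DENSE_LIMIT = 5000


def _cooccurrence(A: np.ndarray, transpose: bool) -> np.ndarray | sp.spmatrix:
    M = A.T if transpose else A
    if M.shape[0] <= _DENSE_LIMIT:
        return M.astype(np.int64) @ M.T.astype(np.int64)
    S = sp.csr_matrix(M.astype(np.int64))
    return S @ S.T


def _edges_from_product(P) -> Iterable[tuple[int, int, int]]:
    if sp.issparse(P):
        C = sp.triu(P.tocoo(), k=1)
        yield from zip(C.row.tolist(), C.col.tolist(), C.data.tolist())
    else:
        iu, ju = np.triu_indices_from(P, k=1)
        w = P[iu, ju]
        nz = w > 0
        yield from zip(iu[nz].tolist(), ju[nz].tolist(), w[nz].tolist())


def project_species(tm: TraitMatrix) -> nx.Graph:
    """Species–species projection ``P = A·Aᵀ``.

    Vertices are all species (isolated ones included, so the graph order is
    ``tm.n_species``) annotated with their family; an edge joins two species
    iff they share at least one trait, weighted by the shared-trait count.
    """
    g = nx.Graph(kind="species")
    for s, fam in zip(tm.species_ids, tm.families):
        g.add_node(s, family=fam)
    P = _cooccurrence(tm.A, transpose=False)
    ids = tm.species_ids
    for i, j, w in _edges_from_product(P):
        g.add_edge(ids[i], ids[j], weight=int(w))
    return g


def project_features(tm: TraitMatrix) -> nx.Graph:
    """Trait–trait projection ``F = Aᵀ·A``; weights count shared species.

    Traits carried by no species pair jointly (e.g. every category of a
    one-of-k trait) remain isolated vertices.
    """
    g = nx.Graph(kind="features")
    g.add_nodes_from(tm.trait_names)
    F = _cooccurrence(tm.A, transpose=True)
    names = tm.trait_names
    for i, j, w in _edges_from_product(F):
        g.add_edge(names[i], names[j], weight=int(w))
    return g


def filter_by_weight(
    g: nx.Graph, min_weight: int, *, drop_isolated: bool = False
) -> nx.Graph:
    """Keep edges with ``weight >= min_weight`` (original weights preserved).

    ``min_weight=2`` realises the "filtered by w_ij > 1" pruning.  With
    ``drop_isolated=True`` vertices left with degree 0 are removed as well —
    the convention for pruned graphs, where only species still connected by
    multiple shared traits count; unpruned graphs keep their isolates.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = g.copy()
    out.remove_edges_from(
        [(u, v) for u, v, w in g.edges(data="weight") if w < min_weight]
    )
    if drop_isolated:
        out.remove_nodes_from([v for v, d in out.degree() if d == 0])
    return out


def connected_components(g: nx.Graph) -> list[set]:
    """Maximal connected vertex sets, largest first (ties by smallest member)."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """TSV edge list ``source<TAB>target<TAB>weight``, deterministically sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(
            (sorted((str(u), str(v))) + [w] for u, v, w in g.edges(data="weight"))
        ):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise ValueError("edge list must start with a source/target/weight header")
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=int(w))
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; family annotations travel as vertex attributes."""
    nx.write_graphml(g, str(path))
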