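"""Cluster-composition accounting and feature-graph summaries.

A :class:`ClusterReport` mirrors the standard composition-table layout:
one row per community, ordered by decreasing species count, with species
and family counts, their percentages against explicit denominators, the
dominant families and per-cluster trait prevalence.  Percentages are
always re-derivable from the printed count and denominator (species % =
100·count/species_denominator to 2 d.p.).

The species denominator is the order of the analysed graph (after any
pruning); the family denominator is the dataset-wide family count, so
family percentages stay comparable across filtered subgraphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx

from .community import Partition
from .trait_data import TraitMatrix, trait_prevalence

__all__ = ["ClusterRow", "ClusterReport", "cluster_report", "feature_report", "FeatureReport"]


@dataclass
class ClusterRow:
    cluster: int  # 1-based rank by decreasing size
    species: list[str]
    species_count: int
    species_pct: float
    family_count: int
    family_pct: float
    dominant_families: list[tuple[str, int]]  # (family, member count), descending
    trait_prevalence: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "species_count": self.species_count,
            "species_pct": self.species_pct,
            "family_count": self.family_count,
            "family_pct": self.family_pct,
            "dominant_families": [list(x) for x in self.dominant_families],
            "trait_prevalence": self.trait_prevalence,
        }


@dataclass
class ClusterReport:
    rows: list[ClusterRow]
    species_denominator: int
    family_denominator: int

    def as_dict(self) -> dict:
        return {
            "species_denominator": self.species_denominator,
            "family_denominator": self.family_denominator,
            "clusters": [r.as_dict() for r in self.rows],
        }

    def to_tsv(self) -> str:
        lines = ["Cluster\tSpecies\t%\tFamilies\t%"]
        for r in self.rows:
            lines.append(
                f"{r.cluster}\t{r.species_count}\t{r.species_pct:.2f}%"
                f"\t{r.family_count}\t{r.family_pct:.2f}%"
            )
        return "\n".join(lines) + "\n"


def percentage(count: int, denominator: int) -> float:
    """Table percentage: 100·count/denominator rounded to 2 d.p."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, 2)


def cluster_report(
    g: nx.Graph,
    p: Partition,
    tm: TraitMatrix,
    *,
    species_denominator: int | None = None,
    family_denominator: int | None = None,
) -> ClusterReport:
    """Per-cluster composition table for a partition of a species graph.

    Clusters are renumbered 1..c by decreasing species count (ties by
    smallest member id).  Defaults: species denominator = graph order,
    family denominator = number of distinct families in the full dataset.
    """
    sden = species_denominator if species_denominator is not None else g.number_of_nodes()
    fden = family_denominator if family_denominator is not None else tm.n_families
    if sden <= 0 or fden <= 0:
        raise ValueError("denominators must be positive")
    fam_of = tm.family_of()
    clusters = p.communities()
    order = sorted(
        range(len(clusters)),
        key=lambda c: (-len(clusters[c]), min(map(str, clusters[c])) if clusters[c] else ""),
    )
    rows: list[ClusterRow] = []
    for rank, c in enumerate(order, start=1):
        members = sorted(map(str, clusters[c]))
        fams: dict[str, int] = {}
        for s in members:
            f = fam_of[s]
            fams[f] = fams.get(f, 0) + 1
        dominant = sorted(fams.items(), key=lambda kv: (-kv[1], kv[0]))
        rows.append(
            ClusterRow(
                cluster=rank,
                species=members,
                species_count=len(members),
                species_pct=percentage(len(members), sden),
                family_count=len(fams),
                family_pct=percentage(len(fams), fden),
                dominant_families=dominant,
                trait_prevalence=trait_prevalence(tm, members),
            )
        )
    return ClusterReport(rows, sden, fden)


@dataclass
class FeatureReport:
    """Feature-graph summary: edges by decreasing shared-species count."""

    ranked_edges: list[tuple[str, str, int]] = field(default_factory=list)
    isolated: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ranked_edges": [list(e) for e in self.ranked_edges],
            "isolated": self.isolated,
        }


def feature_report(fg: nx.Graph) -> FeatureReport:
    """Rank trait pairs by shared-species weight; list isolated traits."""
    edges = sorted(
        (tuple(sorted((str(u), str(v)))) + (int(w),) for u, v, w in fg.edges(data="weight")),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    isolated = sorted(str(v) for v, d in fg.degree() if d == 0)
    return FeatureReport([(u, v, w) for u, v, w in edges], isolated)
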