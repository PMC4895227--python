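"""Species×trait incidence tables: domain types, file I/O and synthetic data.

The central object is :class:`TraitMatrix`, a binary incidence matrix ``A``
with one row per species and one column per trait, together with a family
label per species.  ``A[p, f] = 1`` means species ``p`` carries trait ``f``.
Two trait regimes occur in dispersal-ecology data and both are supported:

* *morphology mode* (``exclusive=False``): traits are independent binary
  attributes (a diaspore can be both flat-winged and elongated);
* *category mode* (``exclusive=True``): traits are one-of-k mutually
  exclusive categories (a fruit has exactly one typology), so every row of
  ``A`` sums to exactly 1.

:class:`SyntheticSpec` + :func:`generate_synthetic` produce trait matrices
with planted structure, emulating real trait databases: species grouped into
families, families assigned to trait profiles, and — because convergent
evolution lets distant families arrive at the same dispersal solution —
several families may share one profile.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "SyntheticSpec",
    "read_trait_table",
    "write_trait_table",
    "generate_synthetic",
    "trait_prevalence",
]


@dataclass
class TraitMatrix:
    """Binary species×trait incidence with family labels.

    Parameters
    ----------
    species_ids
        Ordered unique species identifiers (rows of ``A``).
    families
        Family label per species, aligned with ``species_ids``.
    trait_names
        Ordered unique trait identifiers (columns of ``A``).
    A
        Binary incidence matrix, shape ``(n_species, n_traits)``.
    exclusive
        True when traits are one-of-k categories; every row then sums to 1.
    """

    species_ids: list[str]
    families: list[str]
    trait_names: list[str]
    A: np.ndarray
    exclusive: bool = False

    def __post_init__(self) -> None:
        self.species_ids = list(self.species_ids)
        self.families = list(self.families)
        self.trait_names = list(self.trait_names)
        self.A = np.asarray(self.A, dtype=np.int8)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.A.shape != (len(self.species_ids), len(self.trait_names)):
            raise ValueError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.species_ids)}, {len(self.trait_names)})"
            )
        if len(self.families) != len(self.species_ids):
            raise ValueError("families must have exactly one label per species")
        dup = _first_duplicate(self.species_ids)
        if dup is not None:
            raise ValueError(f"duplicate species id: {dup!r}")
        dup = _first_duplicate(self.trait_names)
        if dup is not None:
            raise ValueError(f"duplicate trait name: {dup!r}")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary (entries 0 or 1)")
        if self.exclusive and not (self.A.sum(axis=1) == 1).all():
            raise ValueError("exclusive trait matrix rows must each sum to exactly 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_families(self) -> int:
        return len(set(self.families))

    def family_of(self) -> dict[str, str]:
        """Map species id → family label."""
        return dict(zip(self.species_ids, self.families))


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header: str) -> str:
    # one dialect: comma or tab, decided from the header line
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_trait_table(
    path: str | Path,
    *,
    mode: str = "binary",
    delimiter: str | None = None,
) -> TraitMatrix:
    """Read a delimited species×trait table.

    The file must carry a header row.  In ``binary`` mode the columns are
    ``species, family, <trait1>, <trait2>, ...`` with 0/1 cells; in
    ``categorical`` mode they are ``species, family, category`` and the single
    category column is one-hot-expanded (categories become traits, sorted
    lexicographically) with ``exclusive=True``.

    Raises
    ------
    ValueError
        On an empty table, a duplicate species id (named in the message), or
        a non-binary cell in binary mode (row and column named).
    """
    if mode not in ("binary", "categorical"):
        raise ValueError(f"mode must be 'binary' or 'categorical', got {mode!r}")
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty trait table: {path}")
    sep = delimiter or _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(
            "trait table needs at least species, family and one trait/category column"
        )
    if df.shape[0] == 0:
        raise ValueError(f"empty trait table: {path}")
    species = df.iloc[:, 0].tolist()
    families = df.iloc[:, 1].tolist()
    dup = _first_duplicate(species)
    if dup is not None:
        raise ValueError(f"duplicate species id: {dup!r}")

    if mode == "categorical":
        if df.shape[1] != 3:
            raise ValueError("categorical mode expects exactly one category column")
        cats = df.iloc[:, 2].tolist()
        trait_names = sorted(set(cats))
        idx = {c: j for j, c in enumerate(trait_names)}
        A = np.zeros((len(species), len(trait_names)), dtype=np.int8)
        for i, c in enumerate(cats):
            A[i, idx[c]] = 1
        return TraitMatrix(species, families, trait_names, A, exclusive=True)

    trait_names = df.columns[2:].tolist()
    A = np.zeros((len(species), len(trait_names)), dtype=np.int8)
    for j, col in enumerate(df.columns[2:]):
        for i, cell in enumerate(df[col]):
            v = cell.strip()
            if v not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell {cell!r} at row {i + 2} (species {species[i]!r}), "
                    f"column {col!r}"
                )
            A[i, j] = int(v)
    return TraitMatrix(species, families, trait_names, A, exclusive=False)


def write_trait_table(
    tm: TraitMatrix,
    path: str | Path,
    *,
    delimiter: str = ",",
    categorical: bool = False,
) -> None:
    """Write a trait matrix as delimited text (inverse of :func:`read_trait_table`).

    With ``categorical=True`` (requires ``tm.exclusive``) the one-hot columns
    collapse back to a single ``category`` column.
    """
    path = Path(path)
    if categorical:
        if not tm.exclusive:
            raise ValueError("categorical output requires an exclusive trait matrix")
        cat_idx = tm.A.argmax(axis=1)
        df = pd.DataFrame(
            {
                "species": tm.species_ids,
                "family": tm.families,
                "category": [tm.trait_names[j] for j in cat_idx],
            }
        )
    else:
        df = pd.DataFrame(tm.A, columns=tm.trait_names)
        df.insert(0, "family", tm.families)
        df.insert(0, "species", tm.species_ids)
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Planted-profile generator specification.

    Each family is assigned one *trait group* (a planted profile); several
    families may map to the same group, modelling evolutionary convergence.
    Species are apportioned evenly across families (remainder going to the
    earliest families) unless ``family_sizes`` pins the per-family counts,
    which lets the generator emulate the skewed family-size distributions of
    real floras.

    Parameters
    ----------
    n_species, n_families
        Counts; families are named ``fam01 .. famNN`` unless
        ``group_of_family`` names them explicitly.
    trait_groups
        Non-empty trait-name lists defining the planted profiles.
    group_of_family
        Optional map family name → index into ``trait_groups``.  Defaults to
        round-robin assignment over generated family names.
    p_in, p_out
        Per-trait carry probabilities inside / outside a species' group
        (``0 ≤ p_out ≤ p_in ≤ 1``).  In exclusive mode ``p_in`` is the
        probability of drawing the single trait from the own group (uniformly
        within it) rather than uniformly from all other traits.
    exclusive
        One-of-k category mode.
    seed
        RNG seed; identical seed+spec reproduce the matrix bit for bit.
    family_sizes
        Optional species count per family (summing to ``n_species``).
    """

    n_species: int
    n_families: int
    trait_groups: list[list[str]]
    p_in: float
    p_out: float
    exclusive: bool = False
    seed: int = 0
    group_of_family: dict[str, int] | None = None
    family_sizes: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_families < 1:
            raise ValueError("n_species and n_families must be positive")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not self.trait_groups or any(len(g) == 0 for g in self.trait_groups):
            raise ValueError("trait groups must be non-empty")
        if self.group_of_family is None:
            fams = [f"fam{i + 1:02d}" for i in range(self.n_families)]
            self.group_of_family = {
                f: i % len(self.trait_groups) for i, f in enumerate(fams)
            }
        else:
            if len(self.group_of_family) != self.n_families:
                raise ValueError("group_of_family must name exactly n_families families")
            for f, g in self.group_of_family.items():
                if not 0 <= g < len(self.trait_groups):
                    raise ValueError(f"family {f!r} maps to unknown trait group {g}")
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_families:
                raise ValueError("family_sizes must have one entry per family")
            if sum(self.family_sizes) != self.n_species:
                raise ValueError("family_sizes must sum to n_species")
            if any(s < 0 for s in self.family_sizes):
                raise ValueError("family sizes must be non-negative")

    @property
    def families(self) -> list[str]:
        assert self.group_of_family is not None
        return list(self.group_of_family)

    @property
    def trait_names(self) -> list[str]:
        names: list[str] = []
        seen: set[str] = set()
        for g in self.trait_groups:
            for t in g:
                if t not in seen:
                    seen.add(t)
                    names.append(t)
        return names


def _apportion(n: int, k: int) -> list[int]:
    """Split n items over k bins as evenly as possible, remainder to the front."""
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_synthetic(spec: SyntheticSpec) -> TraitMatrix:
    """Draw a trait matrix with planted family→trait-group structure.

    Non-exclusive mode: every trait is an independent Bernoulli draw with
    probability ``p_in`` for traits in the species' group and ``p_out``
    otherwise.  Exclusive mode: every species draws exactly one trait —
    with probability ``p_in`` uniformly from its group, otherwise uniformly
    from all remaining traits (if its group covers all traits the in-group
    draw is taken unconditionally).
    """
    rng = np.random.default_rng(spec.seed)
    families = spec.families
    sizes = spec.family_sizes or _apportion(spec.n_species, spec.n_families)
    trait_names = spec.trait_names
    t_index = {t: j for j, t in enumerate(trait_names)}
    n_traits = len(trait_names)

    species_ids: list[str] = []
    fam_labels: list[str] = []
    rows: list[np.ndarray] = []
    width = len(str(spec.n_species))
    counter = 0
    assert spec.group_of_family is not None
    for fam, size in zip(families, sizes):
        group = spec.trait_groups[spec.group_of_family[fam]]
        in_idx = np.array([t_index[t] for t in group], dtype=int)
        out_idx = np.array(
            [j for j in range(n_traits) if j not in set(in_idx.tolist())], dtype=int
        )
        for _ in range(size):
            counter += 1
            species_ids.append(f"sp{counter:0{width}d}")
            fam_labels.append(fam)
            row = np.zeros(n_traits, dtype=np.int8)
            if spec.exclusive:
                if out_idx.size == 0 or rng.random() < spec.p_in:
                    row[rng.choice(in_idx)] = 1
                else:
                    row[rng.choice(out_idx)] = 1
            else:
                row[in_idx] = rng.random(in_idx.size) < spec.p_in
                if out_idx.size:
                    row[out_idx] = rng.random(out_idx.size) < spec.p_out
            rows.append(row)
    A = np.vstack(rows) if rows else np.zeros((0, n_traits), dtype=np.int8)
    return TraitMatrix(species_ids, fam_labels, trait_names, A, exclusive=spec.exclusive)


def planted_morphology_spec(
    n_species: int = 200,
    seed: int = 0,
    *,
    n_groups: int = 4,
    traits_per_group: int = 6,
    n_families: int = 8,
    p_in: float = 0.9,
    p_out: float = 0.05,
) -> SyntheticSpec:
    """Canonical morphology-mode benchmark: planted trait profiles with convergence.

    Four planted profiles of six binary traits each, eight families assigned
    round-robin so that two *distinct* families share every profile — the
    convergent-evolution structure in which clusters come out
    trait-homogeneous but family-heterogeneous.  Profiles span several
    traits so that within-group co-occurrence weights range over small
    integers (1–6) the way real diaspore-morphology data ranges over 1–4,
    and so that a species dropping one profile trait (p_in < 1) stays
    connected to its group.
    """
    groups = [
        [f"m{g}t{k}" for k in range(1, traits_per_group + 1)]
        for g in range(1, n_groups + 1)
    ]
    return SyntheticSpec(
        n_species=n_species,
        n_families=n_families,
        trait_groups=groups,
        p_in=p_in,
        p_out=p_out,
        exclusive=False,
        seed=seed,
    )


def planted_fruit_spec(
    n_species: int = 200,
    seed: int = 0,
    *,
    n_categories: int = 8,
    n_families: int = 8,
    p_in: float = 0.9,
) -> SyntheticSpec:
    """Canonical category-mode benchmark: one-of-k mutually exclusive traits.

    Eight single-category profiles (one per family by default); each species
    draws exactly one category — its family's with probability ``p_in``,
    any other uniformly otherwise.  The species projection of such data is a
    disjoint union of unit-weight cliques and its feature projection is
    edgeless.
    """
    groups = [[f"cat{c}"] for c in range(1, n_categories + 1)]
    return SyntheticSpec(
        n_species=n_species,
        n_families=n_families,
        trait_groups=groups,
        p_in=p_in,
        p_out=0.0,
        exclusive=True,
        seed=seed,
    )


def trait_prevalence(
    tm: TraitMatrix, species_subset: Iterable[str] | None = None
) -> dict[str, int]:
    """Count, per trait, the species of ``species_subset`` carrying it.

    With ``species_subset=None`` the whole matrix is counted.  For an
    exclusive matrix the counts over a subset sum to the subset size; for a
    non-exclusive one they may exceed it, since one species can carry several
    traits.

    Raises
    ------
    KeyError
        If the subset names a species absent from the matrix.
    """
    if species_subset is None:
        idx = np.arange(tm.n_species)
    else:
        pos = {s: i for i, s in enumerate(tm.species_ids)}
        subset = list(species_subset)
        missing = [s for s in subset if s not in pos]
        if missing:
            raise KeyError(f"unknown species id: {missing[0]!r}")
        idx = np.array(sorted(pos[s] for s in set(subset)), dtype=int)
    if idx.size == 0:
        return {t: 0 for t in tm.trait_names}
    counts = tm.A[idx].sum(axis=0)
    return {t: int(c) for t, c in zip(tm.trait_names, counts)}
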