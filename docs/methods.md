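# Methods

## Model and procedure

The analysis treats a trait survey as a bipartite graph: species on one
side, discrete traits on the other, with an edge when a species carries a
trait.  All structure is derived from the binary incidence matrix
`A (n_species × n_traits)`:

* species projection `P = A·Aᵀ`: off-diagonal entry `(i, j)` counts the
  traits species *i* and *j* share; any positive count becomes an edge of
  integer weight `w_ij`.  The diagonal (a species' own trait count) is
  discarded.  Species sharing no trait stay as isolated vertices, so the
  graph order always equals the number of surveyed species.
* feature projection `F = Aᵀ·A`: traits weighted by the number of species
  carrying both.  Traits of a one-of-k categorical scheme can never
  co-occur, so a categorical survey yields an edgeless feature graph and a
  species graph that is a disjoint union of unit-weight cliques (one per
  category) — both degeneracies are asserted in the test suite.

Weights stay raw co-occurrence counts.  No normalisation and no
significance filtering (e.g. hypergeometric null models) is applied; the
only sparsification is the explicit threshold filter `w_ij ≥ t`, exposed
so that "connected by more than one shared trait" is `t = 2`.  When a
pruned graph is analysed, vertices left without edges are dropped (the
surviving-species convention); the unpruned graph keeps its isolates.

Metrics: density `2E/(N(N−1))`; degree `k_i`; strength `s_i` (sum of
incident weights); Barrat weighted local clustering

    c_i = 1/(s_i (k_i − 1)) · Σ_{j,h} ½ (w_ij + w_ih) a_ij a_ih a_jh ,

undefined for `k_i < 2` and reported as missing, never coerced to 0 —
zero-filling would bias every aggregate downward.  Two graph-level
clustering numbers are emitted because the aggregation of the local
quantity is genuinely ambiguous: the mean of defined local coefficients,
and the unweighted transitivity ratio (triangles over connected triples).
Degree and strength distributions are reported as strict CCDFs
`P(X > x)` at every observed value.

Community detection: modularity `Q = Σ_i (e_ii − a_i²)` with `e_ii` the
within-community share of total edge weight and `a_i` the share of edge
ends; an edgeless graph has `Q = 0` by convention.  Four algorithms are
implemented from their published definitions — Clauset–Newman–Moore fast
greedy agglomeration with best-dendrogram-cut selection, Pons–Latapy
walktrap (t-step transition profiles, degree-weighted Euclidean vertex
distance, Ward-style merging of adjacent communities, modularity-optimal
cut), Blondel Louvain (local moves + aggregation), and Raghavan
asynchronous label propagation.  All accept a `weighted` flag; weighted is
the default for projection graphs whose weights carry meaning (shared
counts).  On unit-weight graphs the two modes coincide (tested).

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| `filter_by_weight.min_weight` | caller-set, `t=2` is the "more than one shared trait" prune | threshold semantics `w ≥ t` to avoid the `w > t−1` off-by-one |
| `drop_isolated` | off for unfiltered graphs, on for pruned ones | unfiltered analyses count all surveyed species; pruned analyses count survivors |
| walktrap `t` | 4 | the method's customary short-walk length; cliques give identical answers for any `t` (tested) |
| Louvain stopping tolerance | 1e−12 per full pass | floating-point-safe "no improvement" |
| tie-breaks | CNM: smallest community-id pair; Louvain: seeded shuffled visit order, smallest-id community on equal gain; LP: uniform over the tied label set | reproducibility under a recorded seed |
| percentages | 2 d.p.; densities 7 d.p. | table-display convention; all internal values stay full double |

## The synthetic generator

`SyntheticSpec` plants trait profiles: families are assigned to trait
groups (several families per group = evolutionary convergence), species
are apportioned evenly across families (remainder to the earliest; a
per-family size vector can emulate the skewed family-size distributions
of real floras), and each species draws traits Bernoulli(p_in) inside its
group and Bernoulli(p_out) outside.  In exclusive mode each species draws
exactly one trait — from its group with probability p_in, otherwise
uniformly from the remaining traits.

The canonical study conditions, frozen in
`planted_morphology_spec()` / `planted_fruit_spec()`: 4 profiles,
8 families mapped two-per-profile, n = 200, p_in = 0.9, p_out = 0.05,
seed 0.  Profile size is 6 traits: profiles need several traits so that
(i) within-group co-occurrence weights span small integers the way real
morphology data spans 1–4, and (ii) a group stays cohesive when a species
drops one profile trait — with 2-trait profiles the "only trait A" and
"only trait B" members of one group share nothing, and the planted
partition stops being identifiable by modularity methods at all.

What the generator does *not* emulate: trait correlations beyond the
block structure, the long-tailed family-size distribution (unless
`family_sizes` is given), missing data, and the specific prevalences of
any real database.  Passing recovery tests therefore shows the pipeline
detects planted block structure at realistic noise — not that any real
flora clusters this way.

## Numerical and degenerate-input choices

* Projections use a dense integer matrix product up to 5,000 species and
  a sparse product above — results are identical, only memory differs.
* `density(N, E)` raises for `N < 2`; `graph_metrics` of an empty graph
  reports every field as undefined instead of raising.
* Isolated vertices are singleton communities under every algorithm.
* Cluster reports sort clusters by decreasing size (ties by smallest
  member id) and renumber from 1; the species-percentage denominator is
  the analysed graph's order, the family denominator the dataset-wide
  family count, so family percentages stay comparable across pruned
  subgraphs.
* Pipeline artifacts are written deterministically (sorted edge lists,
  sorted membership tables); the manifest checksums of two runs with the
  same config and seed are identical.

## Known limitations

* Greedy modularity optimisers (CNM, Louvain) are heuristics: on small
  *unstructured* dense random graphs they can land in local optima more
  than 5% below the exhaustive-search optimum, and CNM is deterministic,
  so no run-to-run variation can rescue it.  The test suite pins the
  behaviour that does hold: neither method ever exceeds the exhaustive
  optimum, CNM's best-cut Q is never below the reference implementation's
  on the same graph, and on modular graphs (planted cliques) both reach
  ≥95% of the optimum.
* Label propagation is genuinely stochastic: on two bridged triangles it
  returns the two triangles in 80 of 100 seeded runs (the rest merge
  across the bridge), and on the planted benchmark its recovery varies
  with the seed where the other three algorithms are stable.  It is kept
  because it is part of the standard algorithm battery; conclusions
  should rest on the seeded, reproducible run that is recorded in the
  pipeline log.
* Modularity has a resolution scale; very small planted groups attached
  to a dense background may be absorbed.  No resolution parameter is
  exposed.
* The weighted/unweighted modularity mode used in any published table of
  community counts is rarely stated; both modes are implemented and the
  mode is recorded in the pipeline manifest.
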