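# Methods

## Model

`wavewire` evolves a weighted digraph `G = (V, E, W)` with `|V| = n`,
`|E| = m`, embedded in the unit square. The adjacency convention is
`A[i, j] = w_ij > 0` iff `(j, i) in E` (edge `j -> i`): rows hold incoming
weights, columns outgoing ones. Self-loops are forbidden. Node positions
are fixed for the lifetime of a run; only the topology rewires. Weights
form a conserved multiset under the default policy: a new edge inherits the
weight of the edge it replaces.

Each iteration performs exactly one rewiring:

1. Draw the direction: in-link with probability `p_in`, else out-link.
2. Draw the node `v` uniformly among nodes whose degree in that direction
   lies in `[1, n-2]` — so a removable link and at least one legal new
   partner both exist. Drawing the direction *before* the node is a
   deliberate resolution of an ordering ambiguity: eligibility is
   direction-dependent, so the direction must be known first.
3. Draw the rule from `(p_adaptive, p_wave, p_proximity)` and apply it.

### Adaptive rule

Communication intensity is quantified by the consensus kernel
`c(t) = exp(-L_in t)` and the advection kernel `a(t) = exp(-L_out t)`,
where `L_in = D_in - A` (`D_in` = diagonal of row sums) and
`L_out = D_out - A` (`D_out` = diagonal of column sums). Under the
adjacency convention above these are the unique orientations for which the
consensus kernel is row-stochastic and the advection kernel
column-stochastic — the conservation contracts that make "intensity"
well-defined; both are pinned by tests. `-Lt` is Metzler, so kernel entries
are non-negative and bounded by one.

In-link rewiring of `v` removes the in-neighbour `k` with minimal
`c(t)_vk` and adds the in-link from the non-neighbour `l` (excluding `v`)
with maximal `c(t)_vl`; out-link rewiring reads `a(t)_kv` / `a(t)_lv`. The
kernel is evaluated at `t = tau` and recomputed from scratch (exact dense
matrix exponential, `scipy.linalg.expm`) after every topology change; no
incremental updating is attempted, since the operating regime is n of order
a few hundred at most.

### Wave rule

A wave is a transient perturbation: every existing out-link weight of every
initiator node gains the boost `B`; the whole matrix is divided by its
grand total (unit sum); the adaptive rule then runs on this temporary
matrix; finally all weights revert, the new edge inheriting the removed
edge's pre-boost weight. Initiators are ordinary nodes in every other
respect — they remain selectable as `v`. An initiator that currently has no
out-links contributes no boost (logged as a warning, not an error). With
several initiators all boosts apply simultaneously.

The default initiator set is a single node drawn uniformly from a dedicated
stream derived from the run seed. Keeping that draw out of the main stream
means a configuration with its initiator made explicit replays the exact
same trajectory — which the ensemble runner relies on.

### Proximity rule

Removes the spatially longest link of `v` in the drawn direction and adds
the spatially shortest link to a non-neighbour, using Euclidean distances
in the fixed embedding. Note a subtlety: the rule applies unconditionally,
so when `v`'s links are already the spatially nearest available, the forced
swap can *lengthen* them (the nearest non-neighbour is then farther than
the farthest neighbour). Total wiring length therefore contracts strongly
but not strictly monotonically; the tests assert exactly this conditional
property.

All argmin/argmax ties break toward the lowest node index. Ties have
measure zero for continuous weights but occur in toy graphs, and the rule
makes every trajectory a pure function of the seed.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `n`, `m` | 100, 1000 | nodes and directed edges (both conserved). Chosen so the degree-15 hub threshold is reachable but rare in the initial random graph (mean degree 10); configurable. |
| `M` | 4000 | total rewirings per run |
| `p_in` | 0.5 | probability of rewiring an in-link |
| `p_adaptive`, `p_wave`, `p_proximity` | 1, 0, 0 | rule mix; must sum to 1 |
| `tau` | 1.0 | diffusion time of both kernels (time between rewirings) |
| `B` | 1.0 | additive wave boost on initiator out-link weights |
| `hub_threshold` | 15 | degree threshold; exceedance is strict (`>`), a non-strict variant is a flag |
| `initiators` | one seeded draw | wave initiator node set |
| `weight_policy` | `inherit` | `inherit` keeps the weight multiset invariant; `resample` draws a fresh `N(1, 0.25^2)` weight per rewiring |

Initial weights are `N(1, 0.25^2)`; a negative draw (probability
`Phi(-4) ~ 3.17e-5`) is replaced by 0.05. Only negative draws are clamped —
a positive draw below 0.05 is kept as drawn. Positions are i.i.d. uniform
on `[0, 1]^2`, the simplest isotropic choice for a spatial embedding.

## Measures

* **Modularity.** `Q = (1/2w) sum_ij [w_ij - w_i^in w_j^out/(2w)] delta(C_i, C_j)`
  with `w` the total weight. This `printed` convention is the package
  default. The more common directed convention with `1/w` denominators
  (Leicht-Newman) is available via `convention="leicht_newman"` and is
  cross-checked against networkx; the two differ by scale and null-model
  strength (under `printed`, the one-community partition scores exactly
  1/4, a useful identity pinned in tests). Partitions are found by a
  deterministic two-phase greedy agglomerative search (Louvain-style local
  moves with a seeded node order and a 100-sweep cap, then community
  aggregation, repeated to stability) maximising the selected quality; the
  reported `Q` is always recomputed by an independent direct evaluation of
  the formula on the final labels. On graphs small enough for exhaustive
  partition enumeration the search attains the global optimum in tests.
* **Average efficiency.** Directed shortest paths (Dijkstra) on edge
  lengths `1/w`; unreachable pairs contribute zero; self-pairs excluded.
* **Connected pairs.** Ordered pairs `(i, j)` with a directed path
  `i -> j`. Self-pairs count as connected via the empty path, consistent
  with the `n^2` ceiling.
* **Hubs.** Convergent: in-degree strictly above the threshold and at
  least one out-link. Divergent: mirror image. A node can be both.
* **Convergent-divergent units.** One unit per hub pair `(C, D)` with a
  directed path `C -> D`. The intermediate set is computed by reachability
  intersection — nodes reachable from `C` that also reach `D`, excluding
  the hubs — which contains the union of simple-path interiors and equals
  it unless detour-only nodes exist; both are oracle-tested. Information
  flow is taken convergent-to-divergent. Intermediate-subgraph density is
  the directed edge count over `n_sub (n_sub - 1)/2`; with that
  (half-pair) denominator the value can exceed 1 for strongly reciprocal
  subgraphs. Density is reported only for subgraphs with more than one
  node.

## Ensemble sweeps

`run_ensemble` evolves `R` independently seeded networks per
`(p_proximity, p_wave)` cell (`p_adaptive` is the remainder; cells with
`p_proximity + p_wave > 1` are rejected at validation). Replicate seeds are
`SeedSequence(master_seed, spawn_key=(cell, replicate))`, so results are
invariant to execution order and bit-reproducible. Per cell the runner
reports ensemble means (with standard errors over replicates for the global
measures), initiator-vs-rest degree statistics and hub-formation
proportions, a 1000-draw random non-initiator control for the hub
proportions, convergent-divergent-unit counts and intermediate-subgraph
summaries split by whether the divergent hub is an initiator, and
targeted-vs-non-targeted statistics, where "targeted" means out-neighbours
of initiators in the final network (`scope="ever"` instead accumulates
every node targeted at any point of the run, for sensitivity analysis; the
end-state definition is the default the reported surfaces use). Replicates
whose initiators end with no
out-links have an empty targeted set; they are excluded from targeted means
and counted.

## What the synthetic generator does and does not emulate

All experiments run on internally generated random digraphs: uniform random
topology, near-unit Gaussian weights, uniform spatial positions. This
captures the modelling assumptions — an initially unstructured network with
homogeneous connection strengths — but none of the anatomical structure of
real retinal tissue: no cell-type mosaics, no laminar geometry, no
conduction delays, no growth or pruning (node and edge counts are
conserved throughout), and a single-stage wave process rather than the
multi-stage neurotransmission of real retinal waves. Passing tests
demonstrate the self-organisation properties of the *model* under these
idealised conditions, not quantitative predictions about biological
retinae.

## Problem sizes and test profiles

The full operating point (n=100, m=1000, M=4000, R=30) runs in about a
minute per rule-mix cell, and is used as-is for the favourable-regime
hub-formation check and in `scripts/acceptance.py`. The qualitative
response-surface checks (modularity rising with proximity rewiring,
initiator out-degree ratio rising and in-degree falling with wave
probability, initiator hub formation exceeding the random-node control)
run on a reduced profile — n=60, m=480 (same mean degree of 8–10), M=1500,
R=8, hub threshold 12, on the feasible 4x3 grid
`{0, 0.2, 0.4, 0.6} x {0, 0.2, 0.4}` — which preserves every trend
direction while keeping the default suite fast. Monotonicity is asserted
as one-sided Spearman rank correlation over cell means (p < 0.05).

## Numerical choices and edge cases

* Exact dense `expm`; kernels recomputed per iteration; stochasticity
  contracts hold to 1e-9, series-oracle agreement to 1e-10.
* Degenerate inputs: an edgeless graph has zero Laplacians, so both kernels
  are the identity at every time; modularity on an edgeless graph is an
  explicit error; efficiency of an edgeless graph is 0.
* A complete digraph has no rewiring-eligible node; evolution aborts with
  an error naming the iteration.
* The normalised-Laplacian variant (`laplacian_matrices(..., normalized=True)`)
  is provided for exploration but the unnormalised convention is the model
  default and the only one the contracts pin.
* All randomness flows through `numpy.random.Generator`; every public entry
  point is bit-reproducible from its seed; derived seeds stay below 2^31.

## Known limitations

* The greedy modularity search is a heuristic; on large graphs it returns
  a local optimum (deterministic for a given seed).
* The reachability-intersection definition of intermediate nodes can
  include nodes that only lie on walks (not simple paths) between the
  hubs; such detour-only nodes are rare in practice and the difference is
  surfaced by the oracle tests.
* Weight inheritance on rewiring is an interpretation choice (it preserves
  the stated weight-multiset invariant); resampling is available as a
  config flag for sensitivity analysis.
* The sweep runner is serial; replicates are independent jobs keyed by
  (cell, replicate) and could be parallelised without changing results.
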