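# Methods

## Model

A layout `R = (r_1, …, r_n)`, `r_i = (x_i, y_i) ∈ ℤ²`, assigns every entity
a distinct integer grid point (x rightward, y downward). Layout quality is
the weighted Manhattan cost over unordered pairs

    C(W, R) = Σ_{i<j} w_ij · d_ij,   d_ij = |x_i − x_j| + |y_i − y_j|.

Positive weights pull pairs together, negative weights push them apart.
Manhattan distance (not Euclidean) keeps every candidate-move cost delta an
exact integer computation. Summing each pair once rather than twice scales
the cost by a global factor that cannot change any argmin.

The same machinery runs twice: stage 2 over module points with `W_module`,
stage 3 over nodes with `W_node`.

### Reoptimization after perturbation

`partial_optimize` sweeps entities in insertion order; each entity evaluates
moving to every vacant neighboring point (within its bounds) and commits the
strictly best improving move; sweeps repeat until a full sweep makes no
move. This is steepest single-entity descent, so the cost is non-increasing
and terminates on any bounded board (on an unbounded plane a weight matrix
with net repulsion need not terminate — both pipeline stages are bounded, by
the module board and the module regions respectively). `perturb` then kicks
each entity, independently with probability `perturb_prob`, to a uniformly
random vacant neighboring point. The outer loop keeps whichever of
(current best, re-descended kicked layout) costs less, for `niter` rounds.

Numerical/determinism choices:

* **Neighborhood** — 8-connected (Moore) by default; configurable to
  4-connected (`von_neumann`). Diagonal moves give the compact, roughly
  isotropic layouts the method aims for.
* **Tie-break** — among equally improving moves, scan order
  N, NE, E, SE, S, SW, W, NW wins; sweeps run in entity insertion order.
  Together with one `numpy` PCG64 generator per optimizer call this makes a
  run a pure function of (weights, initial layout, seed).
* **Seed derivation** — a single master seed drives the pipeline; each stage
  draws its own sub-seed (and each stage draws its optimizer seed from its
  placement stream) so initial placements and perturbation sequences never
  share a random stream.
* **Defaults** — `perturb_prob = 0.2`, `niter_module = 200`,
  `niter_grid = 500`. The method's stopping rule is simply a fixed iteration
  budget; these defaults make small instances reliably reach their global
  optimum (verified against exhaustive enumeration on all connected graphs
  with ≤ 4 nodes) while staying interactive on hundred-node networks. All
  are flags.

## Stage 1 — preprocessing

Predefined-module nodes are removed first; multilevel (Louvain) modularity
maximization — delegated to `networkx.community.louvain_communities`, which
is seedable — partitions the induced residual subgraph. Edges from residual
to predefined nodes therefore do not influence clustering. Residual nodes of
degree 0 become singleton pseudo modules. Louvain's resolution parameter
defaults to 1.0 and is exposed (`resolution`) but untouched by the pipeline.

## Stage 2 — module layout

`w_hk = e_hk` (identity on the inter-module edge count): the simplest
mapping that is non-decreasing in `e_hk` and zero at zero; any custom
non-decreasing mapping can be plugged in. Modules start at a seeded random
injective placement on a `⌈√k⌉+1` square board — large enough to hold all
`k` modules with vacancies to move through — and are optimized under
`C_module`. A single module is pinned at the origin.

Region sides use the ceiling, `l_h = max(2, ⌈2√n_h⌉)`, so capacity
`l_h² ≥ 4·n_h` always exceeds the module size; the anchor spacing is
`l′ = max_h l_h + margin` (default margin 2), which guarantees pairwise
disjoint regions separated by a vacant corridor for any distinct integer
module positions.

## Stage 3 — grid optimization

`W_node` is built from shortest-path lengths, computed by breadth-first
search truncated at depth 2 from every node (O(n·m) total): for same-module
pairs, path length 1 → +40, length 2 → 0, length ≥ 3 *or unreachable* →
−10. Pairs in different modules carry no path-length weight; if adjacent
they receive the extra weight +40 (`inter_base="zero"`, the default).

The alternative composition — path-length base for *all* pairs with the
extra accumulated on top (adjacent inter-module pairs at 80) — is available
as `inter_base="path"`. It is not the default because the −10 long-range
repulsion then acts across regions: with dozens of non-adjacent cross-module
pairs it overwhelms a single bridge's +80 attraction and pushes whole
modules (bridge endpoints included) to the far sides of their regions,
inverting the intended pulling behavior. Measured on two 8-node modules
with one bridge: mean bridge gap 6.4 under the default vs 10.5 under the
accumulating variant, against a 9.9 random-placement baseline.

Nodes start at seeded random vacant points of their module's region and are
optimized globally, with moves and kicks hard-constrained to the region
(nodes never leave, even transiently). Disjoint regions then make global
injectivity a per-region concern. Region capacity is validated before
optimization.

## Metrics

* **Connectivity F-measure** — circle membership uses Euclidean distance
  (circles are geometric); `F_i = 1/(α/P_i + (1−α)/R_i)` is maximized
  exactly by evaluating at the distinct distances from node i to all other
  nodes, between which `F_i` is constant. Degree-0 nodes are excluded from
  the average (recall is undefined); `α = 0.5` by default.
* **Relative edge length** — "layout area" is the node bounding box counted
  in grid cells, `(Δx+1)·(Δy+1)`: layout-intrinsic and translation
  invariant.
* **Edge-edge crossings** — two edges cross iff their *open* segments
  intersect: a proper interior crossing, or a collinear overlap of positive
  length (counted once). Segment pairs that merely touch at an endpoint —
  shared nodes and T-junctions — do not cross. Implemented with exact int64
  orientation predicates, vectorized over all `C(m,2)` pairs; tests verify
  it against an independent computational-geometry library.
* **Node-edge crossings** — a non-endpoint node within ε = 0.5 grid units of
  a segment (half a unit cell: the radius below which drawn node glyphs on a
  unit grid cannot overlap an edge they do not touch); normalized by
  `n·m − 2m`. ε is configurable.

## Synthetic data

`generate_modular_network(sizes, p_in, p_out, seed)` draws a planted
partition: intra-module pairs are edges with probability `p_in`,
inter-module pairs with `p_out`. The defaults used throughout the tests —
four modules of 25 nodes, `p_in = 0.3`, `p_out = 0.01` — give expected
intra-module degree ≈ 7 against inter-module degree ≈ 0.75, the
"dense inside, sparse between" regime of real interaction modules. What the
generator does *not* emulate: heavy-tailed degree distributions, overlapping
modules, hierarchical (nested) module structure, and degree correlations —
so passing tests demonstrate correct behavior under clean modular structure,
not performance guarantees on arbitrary real networks.

`example_network_24()` is a fixed 24-node fixture: three densely connected
residual groups bridged by single edges, plus a predefined module
{19, 20, 21, 22, 24} in which node 24 is isolated. Its edge list is a
synthetic repository constant exhibiting those features.

## Problem sizes in the test suite

The acceptance tests run at the sizes their properties are defined on:
optimizer-vs-enumeration on all connected graphs of ≤ 4 nodes on a 4×4
board (100 seeded runs each, `niter = 200`); clustering recovery over 20
seeds of the 100-node planted partition; the GML-vs-random comparison on 10
seeded 100-node networks with `niter_module = 60`, `niter_grid = 40` — a
budget at which the layout quality has long plateaued for this size, chosen
as the package's standard demonstration setting.

## Known limitations

* Greedy single-entity moves cannot swap two entities directly; escaping
  such configurations relies on perturbation, so very small `niter` can
  leave visibly suboptimal layouts.
* Module regions are fixed after stage 2: a poor module placement is not
  revisited during stage 3, and nodes cannot migrate between modules.
* The optimizer cost is O(n) per candidate move with a dense `W_node`;
  networks beyond a few thousand nodes need a sparser weight scheme.
* Predefined modules with low internal density still get a compact square
  region, which can stretch their internal edges.
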