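# Methods

## Graph model

Graphs are simple directed graphs with mandatory vertex labels and
optional edge labels; vertex ids are dense 0-based integers and labels
are arbitrary UTF-8 tokens compared by string equality. Self-loops and
parallel edges are rejected at construction and at parse time: the
molecular and interaction-network graphs this package targets do not
contain them, and excluding them keeps the ordering's candidate sets
(defined over distinct vertices) unambiguous. Undirected graphs are
represented by their symmetric-digraph encoding — each undirected edge
becomes two arcs — so a single matcher covers both cases: the directed
degree filter then collapses to the single undirected inequality on its
own. An "unlabeled" graph is one where every vertex carries the same
reserved label, which removes any special case from the matcher.
"Neighbor" always means adjacency in either direction.

Patterns and targets are assumed connected for matching; the ordering
raises on disconnected or empty patterns, since candidate generation via
parent images requires every vertex after the first to touch the
already-ordered prefix.

## Variable ordering

`greatest_constraint_first` builds the assignment sequence μ greedily.
The start vertex maximizes the distinct-neighbor count. Each later step
scores every unplaced vertex by the lexicographic triple
(|V_vis|, |V_neig|, |V_unv|): prefix members adjacent to the candidate;
prefix members sharing an unplaced neighbor with the candidate; and the
candidate's neighbors not in nor adjacent to the prefix. Maximizing
V_vis first front-loads direct edge constraints, V_neig anticipates
constraints one step ahead, and V_unv breaks remaining ties toward
vertices that open new territory.

Numerical/tie choices made here:

* **Ties** (including the start vertex) break toward the lowest vertex
  id, at every step. This makes the ordering a pure function of the
  pattern and hence testable bit-for-bit.
* **Reciprocal arcs on directed patterns** weigh 2 instead of 1 inside
  score comparisons (a both-direction connection constrains twice).
  The weight applies to the edge incident to the candidate in each
  set's definition; for V_neig, where the set member is a prefix
  vertex, the member weighs 2 when any of its witnesses is linked to
  the candidate by a reciprocal pair. The reported triple stays an
  unweighted cardinality — the weighting lives only in comparisons —
  and on symmetric encodings of undirected graphs it is a no-op.
* The production scorer computes the three quantities by set arithmetic
  over adjacency sets, recomputed per step; pattern graphs in this
  problem family are small (tens to a few hundred vertices), so
  incremental score maintenance buys nothing measurable. Correctness is
  pinned to an independent reimplementation that builds the three sets
  by literal quantifier loops (`rimatch.oracle.naive_ordering`),
  compared exhaustively on all 143 connected graphs with ≤ 6 vertices
  and on seeded directed samples.

Parents are assigned by the smallest-index rule: the parent of v is the
earliest μ-member adjacent to v.

## Matching

The matcher is a depth-first backtracking enumeration in μ order. At
the root, all target vertices are candidates (the ordering's first
vertex has no parent; with domains enabled, its domain is used
instead); at level i ≥ 1, candidates are the direction-blind target
neighbors of the parent's image, intersected with the domain when one
is supplied. Within a level, candidates are tried in ascending target
id, so match emission order is deterministic.

Each candidate pair passes four conditions, evaluated strictly in
order, each only if the previous one held: (1) the target vertex is
unused on the current path; (2) vertex labels are equal; (3) the target
vertex's in-degree and out-degree each dominate the pattern vertex's —
a pure filter that cheaply front-runs the edge check; (4) every pattern
arc between the candidate's vertex and an assigned vertex exists
between their images (with edge-label equality when edge labels are
checked), and in induced mode every target arc between the images is
mirrored by a pattern arc. Edge-label checking is an independent
toggle, off by default: labels on edges only add constraints, and most
workloads carry vertex labels only.

`visited_nodes` counts every (pattern-vertex, target-vertex) pair
submitted to the feasibility check at an expanded node. This is a
definitional choice — search-tree "size" depends on the granularity at
which one counts — and it is used consistently everywhere, so only
relative comparisons (e.g. with vs without domains) are meaningful, not
comparisons against other tools' counters.

Searches accept a wall-clock timeout (default 180 s). Hitting it sets a
flag on the statistics and truncates the stream; it never raises, so
partial results remain usable. A match limit truncates the same way.

## Precomputed domains (`ri-ds`)

`compute_initial_domains` collects, per pattern vertex, the target
vertices with equal label and dominating in/out-degrees.
`filter_edge_compatibility` then makes a **single pass** over the
pattern edges in sorted order: for each arc (u, v), members of D(u)
without an out-neighbor in D(v) are dropped, then members of D(v)
without an in-neighbor in the just-updated D(u). Iterating this to a
fixpoint would be arc-consistency propagation — a different algorithm
family with a different cost profile — so it is deliberately not done;
one sweep is sound (no true match image is ever removed, tested against
the brute-force oracle) and already collapses domains to singletons in
the unique-label regime. During the search, domains are consulted only
as intersection filters and never updated. Consequently the match set
is provably unchanged and the visited-node count can only shrink; both
properties are under test.

## Synthetic benchmark machinery

The generators reproduce, at desk scale, the benchmark families used to
evaluate exact matchers on biochemical-style data. All are pure
functions of their integer seed.

* `random_graph(n, p)`: every (un)ordered vertex pair carries an edge
  independently with probability p.
* `mesh_graph(extents)`: 2D/3D/4D lattices, row-major ids, edges
  between coordinate tuples differing by 1 in one coordinate.
* `bounded_valence_graph(n, d)`: connected d-regular graph, built from
  a circulant seed graph randomized by seeded double-edge swaps (swap
  rounds repeat until connected). A configuration-model pairing with
  retry was tried first and discarded: for the denser valences (d = 9)
  the probability of drawing a simple graph is astronomically small, so
  rejection sampling does not terminate in practice. Only the degree
  histogram and connectivity are contractual, not the sampling law.
* `assign_labels(g, k, distribution)`: per-vertex labels drawn
  uniformly over k symbols, from a discretized gaussian over the label
  indices (mean at the center index, σ = k/6 by default so ±3σ spans
  the alphabet; the distribution was specified as gaussian without
  parameters, so this is the package's choice), or all-unique.
* `extract_pattern(target, spec)`: grows a connected subgraph edge by
  edge. Starting from a seeded random target edge, the frontier is the
  set of target edges incident to the current pattern vertices; one
  frontier edge is pulled in per step until the requested edge budget
  is met. Density steering: when the pattern already holds at least
  `ratio × edges` vertices (ratio 25% / 50% / 90% for
  dense / semidense / sparse), frontier edges internal to the current
  vertex set (closing a cycle) are preferred, otherwise edges bringing
  a new vertex; the non-preferred pool is the fallback when the
  preferred one is empty. For sparse patterns, if the pattern is still
  a tree at the final edge, a cycle-closing edge is forced when one
  exists, so sparse patterns avoid being bare paths/trees. The
  steering is a documented stand-in for an unspecified bias mechanism;
  the contract is that mean vertex/edge ratios are ordered
  dense < semidense < sparse and land within ±20% (relative) of the
  class ratio on sufficiently dense targets — on sparse targets the
  dense class is structurally unreachable (a v-vertex pattern cannot
  hold more than v(v−1)/2 edges). Extracted patterns copy vertex and
  edge labels, and the returned correspondence is guaranteed to be a
  monomorphism of the pattern into the target; the test suite and the
  acceptance script verify this through the matcher itself by pinning
  every domain to the correspondence.

### What the synthetic data does and does not emulate

The generators reproduce the *structural* regimes of the real
benchmarks — label multiplicity, density classes, regular-valence and
lattice topologies — but not the chemistry: real molecular graphs have
valence-constrained label correlations, and real interaction networks
have heavy-tailed degree distributions that uniform-probability random
graphs lack. Passing tests therefore demonstrate algorithmic
correctness and the expected qualitative effort trends, not wall-clock
performance on any published dataset.

## Scales used in the automated checks

The correctness backbone compares the matcher against exhaustive
brute-force enumeration, which is factorial in the instance size; the
checks therefore run 200 seeded instances with targets of ≤ 8 vertices
(edge probability ∈ {0.2, 0.5, 0.8}, 1–4 labels, directed and
undirected alternating) and connected extracted patterns of ≤ 4
vertices — small enough for the oracle, large enough to exercise every
condition and both match modes. The ordering check is exhaustive over
all connected ≤ 6-vertex undirected graphs plus 400–500 seeded directed
samples. The unique-label scaling check uses targets of 50–800 vertices
at mean degree ≈ 8 with 8-edge semidense patterns and asserts a
log–log slope of visited nodes vs target size below 2; the observed
exponent is ≈ 0.1. Density-ratio statistics use 100 seeded extractions
of 64-edge patterns from a 60-vertex, p = 0.6 target, dense enough for
the 25% class to be attainable.

## Known limitations

* Matching time is wall-clock and environment-dependent; only
  visited-node counts are reproducible across machines.
* The matcher recursion depth equals the pattern size; patterns with
  thousands of vertices would need an iterative rewrite.
* No approximate or inexact matching, no VF2-style lookahead rules, no
  propagation-to-convergence filtering — all deliberately out of scope.
* `extract_pattern` may return fewer than the requested edges when the
  reachable component of the start edge is exhausted; callers needing
  the exact budget should check `pattern.n_edges`.
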