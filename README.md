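# rimatch

Subgraph isomorphism search in vertex-labeled graphs, built around a
**static, target-independent variable ordering** and a deliberately
lightweight backtracking matcher, with an optional precomputed-domain
variant and a full synthetic-benchmark toolkit (random / mesh /
bounded-valence targets, density-controlled pattern extraction).

It is aimed at the graph workloads typical of systems biology and
cheminformatics — substructure search in molecular graphs, motif and
complex search in protein–protein interaction networks, contact-map
queries — where graphs carry repeated labels and exhaustive enumeration
of embeddings is the goal.

## The problem and the method

Given a pattern graph *G* = (*V*, *E*) and a target *G′* = (*V′*, *E′*),
both with vertex labels *lab*, a **monomorphism** is an injective map
*M* : *V* → *V′* with *lab*(*u*) = *lab*(*M*(*u*)) for every vertex and
(*M*(*u*), *M*(*v*)) ∈ *E′* for every pattern edge (*u*, *v*) ∈ *E*;
extra target edges among the mapped vertices are allowed. An **induced**
subgraph isomorphism additionally forbids them. The matcher enumerates
all such maps by depth-first traversal of the search-space tree, pruning
with four checks per candidate pair (injectivity, label equality, an
in/out-degree filter, and edge consistency against the assigned prefix).

The search effort is governed by the order in which pattern vertices are
assigned. Before matching, the pattern vertices are arranged into a
sequence μ by a greedy *greatest-constraint-first* rule: the start
vertex has the maximum number of neighbors, and each subsequent choice
maximizes the lexicographic triple

```
( |V_vis| , |V_neig| , |V_unv| )
```

where *V_vis* are μ-members adjacent to the candidate, *V_neig* are
μ-members sharing an unplaced neighbor with it, and *V_unv* are its
fresh neighbors. The ordering depends only on the pattern, is fixed for
every branch, and guarantees (on connected patterns) that every level
after the first is edge-constrained: candidates at level *i* are drawn
only from the target neighbors of the *parent*'s image, the parent being
the earliest μ-member adjacent to μ[i].

The **domains variant** (`ri-ds`) additionally precomputes, once, a
candidate set *D*(*u*) per pattern vertex (label + degree compatibility,
then one sweep over pattern edges removing members with no compatible
neighbor in the opposite domain). Domains act purely as intersection
filters during the search — there is no inference or domain refinement
while backtracking — and they never change the match set, only the
number of visited search nodes.

## Worked example

Generate a 20-vertex labeled random target, extract a connected
5-edge pattern from it, inspect the ordering, and enumerate matches:

```
$ ri gen random --n 20 --p 0.25 --labels 3 --seed 11 -o target.txt
$ ri extract --target target.txt --edges 5 --density semidense --seed 2 \
      --undirected -o pattern.txt
$ ri order pattern.txt --undirected
2 - (0,0,3)
0 2 (1,0,1)
3 2 (1,1,0)
4 0 (2,0,0)
1 2 (1,0,0)
```

Each line is `vertex parent (v_vis, v_neig, v_unv)`: vertex 2 (maximum
degree) starts the sequence, and every later vertex touches the prefix
(`v_vis ≥ 1`), so no level of the search is unconstrained.

```
$ ri match --pattern pattern.txt --target target.txt --undirected --stats
0:7 1:8 2:2 3:18 4:9
0:7 1:12 2:2 3:18 4:9
...
{"visited": 375, "matches": 39, "seconds": 0.001405, "timed_out": false}
```

There are 39 embeddings of the pattern; the search expanded 375
(pattern-vertex, target-vertex) candidate pairs. With precomputed
domains the same 39 matches are found at less than a third of the
effort:

```
$ ri match --pattern pattern.txt --target target.txt --undirected \
      --variant ri-ds --count-only --stats
39
{"visited": 106, "matches": 39, "seconds": 0.000609, "timed_out": false}
```

Batch experiments run through `ri suite --config suite.yaml -o out.csv`,
where the YAML config lists `patterns:`, `targets:`, `variants:`
(`ri`/`ri-ds`), `modes:` (`monomorphism`/`induced`), a `dialect:` and a
`timeout:` (seconds, default 180). The CSV holds one row per run
(visited nodes, match count, matching time — which for `ri-ds` includes
the domain preprocessing — and a timeout flag) followed by per-group
mean/SD aggregates; timed-out runs are excluded from the means.

The same functionality is available as a library:

```python
from rimatch import read_graph, find_matches, MatchMode, compute_domains

pattern = read_graph("pattern.txt", "undirected")
target = read_graph("target.txt", "undirected")
run = find_matches(pattern, target, MatchMode("monomorphism"),
                   domains=compute_domains(pattern, target))
for m in run:
    print(m.targets)
print(run.stats.visited_nodes, run.stats.n_matches)
```

## Graph file format

One graph per file: a `#name` header, the vertex count, one label token
per vertex, the edge count, then one `u v [edge_label]` line per edge.
Directedness is chosen by the reader (`--undirected` flag); undirected
edges are stored internally as symmetric arc pairs.

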