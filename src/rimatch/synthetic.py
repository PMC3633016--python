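"""Synthetic benchmark machinery: targets, labels, and extracted patterns.

Mirrors the benchmark families typical of molecular and interaction-
network matching studies:

* uniform-probability random graphs (Erdős–Rényi style),
* 2D/3D/4D mesh lattices,
* bounded-valence (regular-degree) random graphs,
* vertex labels drawn uniformly, from a discretized gaussian over the
  label alphabet, or all-unique,
* connected patterns grown edge-by-edge out of a target, steered toward
  a density class — dense, semidense, sparse — defined by the ratio of
  vertices to edges (~25%, ~50%, ~90%).

Every generator is a pure function of its seed.  Extracted patterns are
guaranteed monomorphic images of their target: the returned vertex
correspondence is itself a valid match.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from .graph import LabeledGraph, from_undirected_edges

DENSITY_RATIO = {"dense": 0.25, "semidense": 0.50, "sparse": 0.90}

DEFAULT_LABEL = "A"  # shared dummy label: the "unlabeled" regime


@dataclass(frozen=True)
class PatternSpec:
    """Request for one extracted pattern: edge budget, density class, seed."""

    n_edges: int
    density_class: str = "semidense"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges < 1:
            raise ValueError("n_edges must be >= 1")
        if self.density_class not in DENSITY_RATIO:
            raise ValueError(f"unknown density class {self.density_class!r}")


# -- target generators ----------------------------------------------------


def random_graph(
    n: int, p: float, directed: bool = False, seed: int = 0, name: Optional[str] = None
) -> LabeledGraph:
    """Uniform-edge-probability random graph.

    Each vertex pair (ordered if ``directed``, else unordered then
    symmetrized) carries an edge independently with probability ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability {p} outside [0, 1]")
    if n < 0:
        raise ValueError("negative vertex count")
    rng = np.random.default_rng(seed)
    name = name or f"random-n{n}-p{p}-s{seed}"
    labels = [DEFAULT_LABEL] * n
    if directed:
        us, vs = np.nonzero(rng.random((n, n)) < p)
        edges = {(int(u), int(v)) for u, v in zip(us, vs) if u != v}
        return LabeledGraph(name, n, True, labels, edges)
    mask = np.triu(rng.random((n, n)) < p, k=1)
    us, vs = np.nonzero(mask)
    pairs = [(int(u), int(v)) for u, v in zip(us, vs)]
    return from_undirected_edges(name, labels, pairs)


def mesh_graph(side_lengths: tuple[int, ...], name: Optional[str] = None) -> LabeledGraph:
    """2D/3D/4D lattice: vertices are coordinate tuples (row-major ids),
    undirected edges join tuples differing by 1 in exactly one coordinate."""
    dims = len(side_lengths)
    if dims not in (2, 3, 4):
        raise ValueError(f"mesh dimensionality must be 2-4, got {dims}")
    if any(s < 2 for s in side_lengths):
        raise ValueError("every mesh extent must be >= 2")
    name = name or ("mesh-" + "x".join(map(str, side_lengths)))
    coords = list(product(*(range(s) for s in side_lengths)))
    index = {c: i for i, c in enumerate(coords)}
    pairs = []
    for c in coords:
        for axis in range(dims):
            if c[axis] + 1 < side_lengths[axis]:
                succ = c[:axis] + (c[axis] + 1,) + c[axis + 1 :]
                pairs.append((index[c], index[succ]))
    return from_undirected_edges(name, [DEFAULT_LABEL] * len(coords), pairs)


def bounded_valence_graph(
    n: int, valence: int, seed: int = 0, name: Optional[str] = None, max_rounds: int = 50
) -> LabeledGraph:
    """Connected random graph with every vertex of the same degree.

    Construction: start from a circulant graph (vertex ``i`` joined to
    ``i +- 1 .. i +- valence//2``, plus the antipode when the valence is
    odd), then randomize with seeded double-edge swaps that preserve the
    degree sequence and reject self-loops and parallel edges; swap rounds
    repeat until the graph is connected.  Only the degree postcondition
    (and connectivity) is contractual, not the exact sampling law.
    """
    if valence < 1:
        raise ValueError("valence must be >= 1")
    if n <= valence:
        raise ValueError(f"need n > valence, got n={n}, valence={valence}")
    if (n * valence) % 2 != 0:
        raise ValueError(f"n * valence must be even (n={n}, valence={valence})")
    rng = np.random.default_rng(seed)
    name = name or f"valence-n{n}-d{valence}-s{seed}"

    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        for k in range(1, valence // 2 + 1):
            j = (i + k) % n
            pairs.add((min(i, j), max(i, j)))
        if valence % 2 == 1:  # parity guarantees n even here
            j = (i + n // 2) % n
            pairs.add((min(i, j), max(i, j)))

    n_swaps = 10 * len(pairs)
    for _ in range(max_rounds):
        edge_list = sorted(pairs)
        for _ in range(n_swaps):
            i1, i2 = rng.integers(len(edge_list), size=2)
            old1, old2 = edge_list[int(i1)], edge_list[int(i2)]
            a, b = old1
            c, d = old2 if rng.random() < 0.5 else old2[::-1]
            # rewire (a,b),(c,d) -> (a,c),(b,d)
            if len({a, b, c, d}) < 4:
                continue
            e1 = (min(a, c), max(a, c))
            e2 = (min(b, d), max(b, d))
            if e1 in pairs or e2 in pairs:
                continue
            pairs.discard(old1)
            pairs.discard(old2)
            pairs.update((e1, e2))
            edge_list[int(i1)] = e1
            edge_list[int(i2)] = e2
        g = from_undirected_edges(name, [DEFAULT_LABEL] * n, sorted(pairs))
        if g.is_connected():
            return g
    raise RuntimeError(
        f"could not reach a connected {valence}-regular graph on {n} vertices"
    )


# -- labels ---------------------------------------------------------------


def assign_labels(
    g: LabeledGraph,
    n_labels: int,
    distribution: str = "uniform",
    seed: int = 0,
    sigma: Optional[float] = None,
) -> LabeledGraph:
    """Return a copy of ``g`` with freshly drawn vertex labels.

    ``uniform`` draws each vertex's label equiprobably from ``n_labels``
    symbols; ``normal`` draws with probabilities proportional to a
    discretized gaussian over the label indices (mean at the center,
    ``sigma`` defaulting to ``n_labels / 6`` so ±3 sigma spans the
    alphabet); ``unique`` gives every vertex its own label (``n_labels``
    is ignored and taken as the vertex count).
    """
    if distribution not in ("uniform", "normal", "unique"):
        raise ValueError(f"unknown label distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    n = g.n_vertices
    if distribution == "unique":
        labels = [f"L{i}" for i in rng.permutation(n)]
    else:
        if n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        if distribution == "uniform":
            idx = rng.integers(0, n_labels, size=n)
        else:
            s = sigma if sigma is not None else n_labels / 6.0
            centers = np.arange(n_labels, dtype=float)
            weights = np.exp(-((centers - (n_labels - 1) / 2.0) ** 2) / (2.0 * s * s))
            idx = rng.choice(n_labels, size=n, p=weights / weights.sum())
        labels = [f"L{int(i)}" for i in idx]
    return LabeledGraph(
        name=g.name,
        n_vertices=n,
        directed=g.directed,
        vertex_labels=labels,
        edges=set(g.edges),
        edge_labels=dict(g.edge_labels) if g.edge_labels is not None else None,
    )


# -- pattern extraction ---------------------------------------------------


def _undirected_pairs(g: LabeledGraph) -> set[tuple[int, int]]:
    return {(min(u, v), max(u, v)) for u, v in g.edges}


def extract_pattern(
    target: LabeledGraph, spec: PatternSpec
) -> tuple[LabeledGraph, dict[int, int]]:
    """Grow a connected pattern out of ``target`` by repeated edge pulls.

    Starting from a random target edge, edges adjacent to the current
    pattern (the frontier) are pulled in one at a time until the edge
    budget is met.  The vertex/edge ratio is steered toward the density
    class: when the pattern already holds at least ``ratio * edges``
    vertices, frontier edges internal to the pattern (closing a cycle)
    are preferred, otherwise edges bringing a new vertex.  Edge counts
    are in adjacency-pair units — a symmetric arc pair is one edge.

    Returns the pattern (labels copied from the target) and the vertex
    correspondence pattern-id -> target-id, which is always a valid
    monomorphism of the pattern into the target.
    """
    all_pairs = _undirected_pairs(target)
    if len(all_pairs) < spec.n_edges:
        raise ValueError(
            f"target has {len(all_pairs)} edges, fewer than requested {spec.n_edges}"
        )
    rng = np.random.default_rng(spec.seed)
    ratio = DENSITY_RATIO[spec.density_class]

    pairs_sorted = sorted(all_pairs)
    first = pairs_sorted[int(rng.integers(len(pairs_sorted)))]
    pat_vertices: set[int] = set(first)
    pat_pairs: set[tuple[int, int]] = {first}

    # frontier bookkeeping: target pairs incident to the pattern, unused
    def incident_pairs(v: int) -> set[tuple[int, int]]:
        return {(min(v, w), max(v, w)) for w in target.neighbors(v)}

    frontier: set[tuple[int, int]] = set()
    for v in pat_vertices:
        frontier |= incident_pairs(v)
    frontier -= pat_pairs

    while len(pat_pairs) < spec.n_edges and frontier:
        closing = sorted(
            e for e in frontier if e[0] in pat_vertices and e[1] in pat_vertices
        )
        closing_set = set(closing)
        expanding = sorted(e for e in frontier if e not in closing_set)
        desired_vertices = ratio * (len(pat_pairs) + 1)
        last_edge = len(pat_pairs) == spec.n_edges - 1
        is_tree = len(pat_vertices) == len(pat_pairs) + 1
        if spec.density_class == "sparse" and last_edge and is_tree and closing:
            pool = closing  # avoid pure trees/paths: close one cycle
        elif len(pat_vertices) >= desired_vertices and closing:
            pool = closing
        elif expanding:
            pool = expanding
        else:
            pool = closing
        e = pool[int(rng.integers(len(pool)))]
        pat_pairs.add(e)
        frontier.discard(e)
        for v in e:
            if v not in pat_vertices:
                pat_vertices.add(v)
                frontier |= incident_pairs(v) - pat_pairs

    tids = sorted(pat_vertices)
    to_pattern = {t: i for i, t in enumerate(tids)}
    edges: set[tuple[int, int]] = set()
    edge_labels: Optional[dict[tuple[int, int], str]] = (
        {} if target.edge_labels is not None else None
    )
    for a, b in pat_pairs:
        for u, v in ((a, b), (b, a)):
            if target.has_edge(u, v):
                pe = (to_pattern[u], to_pattern[v])
                edges.add(pe)
                if edge_labels is not None:
                    edge_labels[pe] = target.edge_labels[(u, v)]
    pattern = LabeledGraph(
        name=f"{target.name}-pat-e{spec.n_edges}-{spec.density_class}-s{spec.seed}",
        n_vertices=len(tids),
        directed=target.directed,
        vertex_labels=[target.vertex_labels[t] for t in tids],
        edges=edges,
        edge_labels=edge_labels,
    )
    correspondence = {i: t for i, t in enumerate(tids)}
    return pattern, correspondence
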