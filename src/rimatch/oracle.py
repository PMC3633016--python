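"""Brute-force reference implementations, for testing only.

These share no code with the ordering or the backtracking matcher: every
injective map is enumerated outright and checked against the match
definition, and the ordering scores are rebuilt literally from their set
definitions.  Slow by construction — size guards keep the factorial
blow-up in check.
"""

from __future__ import annotations

from itertools import permutations

from .graph import LabeledGraph
from .matching import Mapping, MatchMode
from .ordering import ScoreTriple

MAX_PATTERN = 8
MAX_TARGET = 10


def brute_force_matches(
    pattern: LabeledGraph, target: LabeledGraph, mode: MatchMode
) -> set[Mapping]:
    """All valid complete mappings by exhaustive enumeration.

    Checks labels, every pattern edge (with edge labels when enabled),
    and the induced condition when selected.  No ordering, no parents,
    no domains, no degree shortcuts.
    """
    n, m = pattern.n_vertices, target.n_vertices
    if n > MAX_PATTERN or m > MAX_TARGET:
        raise ValueError(
            f"instance too large for brute force ({n} pattern / {m} target vertices)"
        )
    found: set[Mapping] = set()
    for image in permutations(range(m), n):
        ok = True
        for u in range(n):
            if pattern.vertex_labels[u] != target.vertex_labels[image[u]]:
                ok = False
                break
        if not ok:
            continue
        for u, v in pattern.edges:
            if (image[u], image[v]) not in target.edges:
                ok = False
                break
            if mode.edge_labels_checked and pattern.edge_label(
                u, v
            ) != target.edge_label(image[u], image[v]):
                ok = False
                break
        if ok and mode.induced:
            for u in range(n):
                for v in range(n):
                    if u != v and (image[u], image[v]) in target.edges:
                        if (u, v) not in pattern.edges:
                            ok = False
                            break
                if not ok:
                    break
        if ok:
            found.add(Mapping(image))
    return found


def naive_score_sets(
    pattern: LabeledGraph, mu_prefix: list[int], candidate: int
) -> ScoreTriple:
    """The three ordering sets built by literal quantifier loops.

    Used to pin the production scorer; intentionally quadratic.
    """

    def adjacent(a: int, b: int) -> bool:
        return (a, b) in pattern.edges or (b, a) in pattern.edges

    m = len(mu_prefix)
    outside = [v for v in range(pattern.n_vertices) if v not in mu_prefix and v != candidate]

    vis = [u for u in mu_prefix if adjacent(candidate, u)]
    neig = []
    for u in mu_prefix:
        if any(adjacent(u, j) and adjacent(candidate, j) for j in outside):
            neig.append(u)
    unv = []
    for j in outside:
        if adjacent(candidate, j) and not any(adjacent(u, j) for u in mu_prefix):
            unv.append(j)

    if not pattern.directed:
        return ScoreTriple(len(vis), len(neig), len(unv), len(vis), len(neig), len(unv))

    def weight(other: int) -> int:
        if (candidate, other) in pattern.edges and (other, candidate) in pattern.edges:
            return 2
        return 1

    w_vis = sum(weight(u) for u in vis)
    w_unv = sum(weight(j) for j in unv)
    w_neig = 0
    for u in neig:
        w_neig += max(
            weight(j) for j in outside if adjacent(u, j) and adjacent(candidate, j)
        )
    return ScoreTriple(len(vis), len(neig), len(unv), w_vis, w_neig, w_unv)


def naive_ordering(pattern: LabeledGraph) -> list[int]:
    """Greedy ordering recomputing every score from scratch each step."""
    if pattern.n_vertices == 0 or not pattern.is_connected():
        raise ValueError("pattern must be nonempty and connected")
    degs = [len({v for (a, v) in pattern.edges if a == u}
                | {a for (a, v) in pattern.edges if v == u})
            for u in range(pattern.n_vertices)]
    start = max(range(pattern.n_vertices), key=lambda u: (degs[u], -u))
    mu = [start]
    while len(mu) < pattern.n_vertices:
        best = None
        best_key = None
        for u in range(pattern.n_vertices):
            if u in mu:
                continue
            s = naive_score_sets(pattern, mu, u)
            key = (s.sort_key(), -u)
            if best_key is None or key > best_key:
                best, best_key = u, key
        mu.append(best)
    return mu
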