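"""Static, target-independent pattern-vertex ordering (GreatestConstraintFirst).

Before the search starts, the pattern's vertices are arranged into a fixed
sequence mu so that each newly assigned vertex carries as many edge
constraints against the already-assigned prefix as possible, as early as
possible.  The ordering is greedy: the start vertex has the maximum number
of neighbors, and each subsequent vertex maximizes the lexicographic score

    (|V_vis|, |V_neig|, |V_unv|)

where, for a candidate u_m against the current prefix mu:

* ``V_vis``  — prefix members adjacent to u_m (direct constraints);
* ``V_neig`` — prefix members sharing an unplaced neighbor with u_m
  (constraints one step ahead);
* ``V_unv``  — u_m's neighbors that are neither in the prefix nor adjacent
  to it (fresh territory).

"Neighbor" always ignores edge direction.  On directed patterns a set
member whose connecting edge to the candidate is reciprocal (both arcs
present) weighs 2 instead of 1, but only inside score comparisons — the
reported triple stays a plain cardinality.  All ties (including the start
vertex) break toward the lowest vertex id, making the ordering
deterministic.

Each vertex also records a *parent*: the earliest prefix member adjacent
to it.  During matching, candidates for a vertex are drawn from the target
neighbors of its parent's image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .graph import LabeledGraph


@dataclass(frozen=True)
class ScoreTriple:
    """Lexicographic ordering score of one candidate vertex.

    ``v_vis``, ``v_neig``, ``v_unv`` are the exact set cardinalities; the
    private weighted counterparts (reciprocal directed edges counted
    twice) drive comparisons on directed patterns.
    """

    v_vis: int
    v_neig: int
    v_unv: int
    w_vis: int = -1
    w_neig: int = -1
    w_unv: int = -1

    def sort_key(self) -> tuple[int, int, int]:
        if self.w_vis >= 0:
            return (self.w_vis, self.w_neig, self.w_unv)
        return (self.v_vis, self.v_neig, self.v_unv)

    def __lt__(self, other: "ScoreTriple") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "ScoreTriple") -> bool:
        return self.sort_key() <= other.sort_key()


@dataclass(frozen=True)
class VariableOrdering:
    """Output of the ordering phase: sequence ``mu`` plus parent pointers.

    ``mu`` is a permutation of the pattern's vertex ids; ``parent[v]`` is
    the earliest mu-member adjacent to ``v`` (``None`` for ``mu[0]``).
    """

    mu: tuple[int, ...]
    parent: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if sorted(self.mu) != list(range(len(self.mu))):
            raise ValueError("mu is not a permutation of the vertex ids")
        if len(self.parent) != len(self.mu):
            raise ValueError("parent table length differs from mu")


def score_candidate(
    pattern: LabeledGraph, mu_prefix: Sequence[int], candidate: int
) -> ScoreTriple:
    """Score ``candidate`` against the partial ordering ``mu_prefix``."""
    if candidate in mu_prefix:
        raise ValueError(f"candidate {candidate} already in the prefix")
    pattern._check_vertex(candidate)
    placed = set(mu_prefix)
    cand_nb = pattern.neighbors(candidate)

    vis = cand_nb & placed
    # unplaced neighbors of the candidate, split by whether they touch mu
    witnesses = {j for j in cand_nb - placed if pattern.neighbors(j) & placed}
    unv = (cand_nb - placed) - witnesses
    neig = {i for i in placed if pattern.neighbors(i) & witnesses}

    if not pattern.directed:
        n_vis, n_neig, n_unv = len(vis), len(neig), len(unv)
        return ScoreTriple(n_vis, n_neig, n_unv, n_vis, n_neig, n_unv)

    def w(other: int) -> int:
        # reciprocal pair candidate<->other counts double
        both = pattern.has_edge(candidate, other) and pattern.has_edge(other, candidate)
        return 2 if both else 1

    w_vis = sum(w(i) for i in vis)
    w_unv = sum(w(j) for j in unv)
    w_neig = 0
    for i in neig:
        member_witnesses = pattern.neighbors(i) & witnesses
        w_neig += max(w(j) for j in member_witnesses)
    return ScoreTriple(len(vis), len(neig), len(unv), w_vis, w_neig, w_unv)


def greatest_constraint_first(pattern: LabeledGraph) -> VariableOrdering:
    """Compute the full ordering for a connected pattern.

    Raises ``ValueError`` on an empty or disconnected pattern: the search
    draws candidates from parent images, which requires every vertex after
    the first to touch the prefix.
    """
    n = pattern.n_vertices
    if n == 0:
        raise ValueError("empty pattern")
    if not pattern.is_connected():
        raise ValueError("pattern must be connected")

    # start vertex: maximum distinct-neighbor count, lowest id on ties
    u0 = min(range(n), key=lambda u: (-pattern.degree(u), u))
    mu = [u0]
    remaining = set(range(n)) - {u0}
    while remaining:
        best = min(
            remaining,
            key=lambda u: tuple(-c for c in score_candidate(pattern, mu, u).sort_key())
            + (u,),
        )
        mu.append(best)
        remaining.discard(best)

    parent: list[Optional[int]] = [None] * n
    for pos in range(1, n):
        v = mu[pos]
        nb = pattern.neighbors(v)
        parent[v] = next(mu[i] for i in range(pos) if mu[i] in nb)
    return VariableOrdering(mu=tuple(mu), parent=tuple(parent))
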