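"""Backtracking subgraph matcher.

Depth-first traversal of the search-space tree in the fixed order mu.
At level ``i`` the candidates for pattern vertex ``mu[i]`` are the target
neighbors of the image of its parent (all target vertices at the root),
optionally intersected with precomputed per-vertex domains.  Each
candidate is screened by four conditions, cheapest first:

1. the target vertex is not already used on the current path;
2. vertex labels agree;
3. the target vertex's in- and out-degrees are at least the pattern
   vertex's (a pure filter — it can only reject, never certify);
4. every pattern edge between the new vertex and an already-assigned one
   has its counterpart in the target (with edge-label equality when
   requested); in induced mode, target edges between assigned images must
   be mirrored by pattern edges as well.

A *monomorphism* allows extra target edges among the mapped vertices; an
*induced* isomorphism forbids them.  No inference or domain refinement
happens during the search — pruning comes from the ordering, which fronts
edge-constrained vertices.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .domains import DomainTable
from .graph import LabeledGraph
from .ordering import VariableOrdering, greatest_constraint_first

DEFAULT_TIMEOUT = 180.0  # seconds; total-execution cap applied per search

MONOMORPHISM = "monomorphism"
INDUCED = "induced"


@dataclass(frozen=True)
class MatchMode:
    """What counts as a match: mono vs induced, and edge-label strictness."""

    kind: str = MONOMORPHISM
    edge_labels_checked: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (MONOMORPHISM, INDUCED):
            raise ValueError(f"unknown match kind {self.kind!r}")

    @property
    def induced(self) -> bool:
        return self.kind == INDUCED


@dataclass(frozen=True)
class Mapping:
    """A complete injective assignment of pattern to target vertices.

    ``targets[u]`` is the target image of pattern vertex ``u``.
    """

    targets: tuple[int, ...]

    def __getitem__(self, u: int) -> int:
        return self.targets[u]

    def __len__(self) -> int:
        return len(self.targets)

    def as_dict(self) -> dict[int, int]:
        return dict(enumerate(self.targets))


@dataclass
class SearchStats:
    """Search effort accounting.

    ``visited_nodes`` counts every (pattern-vertex, target-vertex) pair
    submitted to the feasibility check at an expanded node — the
    hardware-independent measure of search-space size.
    """

    visited_nodes: int = 0
    n_matches: int = 0
    elapsed: float = 0.0
    timed_out: bool = False


def candidate_targets(
    target: LabeledGraph,
    ordering: VariableOrdering,
    partial: dict[int, int],
    i: int,
    domains: Optional[DomainTable] = None,
) -> set[int]:
    """Candidate target vertices for pattern vertex ``mu[i]``.

    The root level scans all target vertices; deeper levels scan the
    (direction-blind) target neighbors of the parent's image.  Domains,
    when given, act as intersection filters only.
    """
    u = ordering.mu[i]
    par = ordering.parent[u]
    if par is None:
        cands = set(range(target.n_vertices))
    else:
        cands = set(target.neighbors(partial[par]))
    if domains is not None:
        cands &= domains[u]
    return cands


def is_feasible(
    pattern: LabeledGraph,
    target: LabeledGraph,
    partial: dict[int, int],
    u: int,
    t: int,
    mode: MatchMode,
) -> bool:
    """Test the four conditions, strictly in order, for extending
    ``partial`` with ``u -> t``."""
    # 1. injectivity on the current path
    if t in partial.values():
        return False
    # 2. vertex-label compatibility
    if pattern.vertex_labels[u] != target.vertex_labels[t]:
        return False
    # 3. degree filter, each direction separately
    if target.in_degree(t) < pattern.in_degree(u):
        return False
    if target.out_degree(t) < pattern.out_degree(u):
        return False
    # 4. edge constraints against the assigned prefix
    for v, tv in partial.items():
        if pattern.has_edge(u, v):
            if not target.has_edge(t, tv):
                return False
            if mode.edge_labels_checked and pattern.edge_label(
                u, v
            ) != target.edge_label(t, tv):
                return False
        elif mode.induced and target.has_edge(t, tv):
            return False
        if pattern.has_edge(v, u):
            if not target.has_edge(tv, t):
                return False
            if mode.edge_labels_checked and pattern.edge_label(
                v, u
            ) != target.edge_label(tv, t):
                return False
        elif mode.induced and target.has_edge(tv, t):
            return False
    return True


@dataclass
class MatchRun:
    """Lazy stream of matches with live :class:`SearchStats`.

    Iterate to drain matches; ``stats`` is updated as the search runs and
    is final once iteration stops (exhaustion, ``limit``, or timeout).
    """

    pattern: LabeledGraph
    target: LabeledGraph
    mode: MatchMode
    ordering: VariableOrdering
    domains: Optional[DomainTable]
    timeout: Optional[float]
    limit: Optional[int]
    stats: SearchStats = field(default_factory=SearchStats)

    def __iter__(self) -> Iterator[Mapping]:
        start = time.monotonic()
        stats = self.stats
        mu = self.ordering.mu
        n = len(mu)

        if self.domains is not None and any(
            len(self.domains[u]) == 0 for u in range(n)
        ):
            stats.elapsed = time.monotonic() - start
            return

        partial: dict[int, int] = {}

        def dfs(level: int) -> Iterator[Mapping]:
            if level == n:
                stats.n_matches += 1
                yield Mapping(tuple(partial[u] for u in range(n)))
                return
            u = mu[level]
            for t in sorted(
                candidate_targets(self.target, self.ordering, partial, level, self.domains)
            ):
                if self.timeout is not None and time.monotonic() - start > self.timeout:
                    stats.timed_out = True
                    return
                stats.visited_nodes += 1
                if is_feasible(self.pattern, self.target, partial, u, t, self.mode):
                    partial[u] = t
                    yield from dfs(level + 1)
                    del partial[u]
                    if stats.timed_out:
                        return
                    if self.limit is not None and stats.n_matches >= self.limit:
                        return

        try:
            yield from dfs(0)
        finally:
            stats.elapsed = time.monotonic() - start


def find_matches(
    pattern: LabeledGraph,
    target: LabeledGraph,
    mode: MatchMode = MatchMode(),
    ordering: Optional[VariableOrdering] = None,
    domains: Optional[DomainTable] = None,
    timeout: Optional[float] = DEFAULT_TIMEOUT,
    limit: Optional[int] = None,
) -> MatchRun:
    """Set up a match enumeration; the ordering defaults to
    :func:`greatest_constraint_first` on the pattern.

    Returns a :class:`MatchRun`; matches are produced lazily in
    depth-first discovery order (ascending target id within a level).
    A timeout flags ``stats.timed_out`` and truncates the stream instead
    of raising.
    """
    if ordering is None:
        ordering = greatest_constraint_first(pattern)
    return MatchRun(
        pattern=pattern,
        target=target,
        mode=mode,
        ordering=ordering,
        domains=domains,
        timeout=timeout,
        limit=limit,
    )


def enumerate_matches(
    pattern: LabeledGraph,
    target: LabeledGraph,
    mode: MatchMode = MatchMode(),
    **kwargs,
) -> tuple[list[Mapping], SearchStats]:
    """Eagerly collect all matches; convenience over :func:`find_matches`."""
    run = find_matches(pattern, target, mode, **kwargs)
    matches = list(run)
    return matches, run.stats


def count_matches(
    pattern: LabeledGraph,
    target: LabeledGraph,
    mode: MatchMode = MatchMode(),
    **kwargs,
) -> tuple[int, SearchStats]:
    """Count matches without materializing the mappings."""
    run = find_matches(pattern, target, mode, **kwargs)
    count = sum(1 for _ in run)
    return count, run.stats
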