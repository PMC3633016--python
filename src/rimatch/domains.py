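"""Initial candidate domains (the RI-Ds variant's preprocessing).

Before the search begins, each pattern vertex u gets a *domain*: the set
of target vertices compatible with it a priori — equal label, and target
in- and out-degrees at least the pattern's.  A second single pass over
the pattern's edges then drops domain members with no suitably-directed
neighbor in the opposite endpoint's domain.

Both passes are sound (no true match image is ever removed) and run
once, before backtracking; the search consults domains purely as
intersection filters and never refines them.  Repeating the edge pass to
a fixpoint would amount to full arc-consistency propagation, which this
design deliberately avoids: the point is a cheap pre-filter, not
inference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import LabeledGraph


@dataclass
class DomainTable:
    """Per-pattern-vertex candidate sets ``D(u)`` over target vertex ids."""

    domains: list[set[int]]

    def __getitem__(self, u: int) -> set[int]:
        return self.domains[u]

    def __len__(self) -> int:
        return len(self.domains)

    def is_empty(self) -> bool:
        """True when some vertex has no candidates (hence zero matches)."""
        return any(not d for d in self.domains)

    def copy(self) -> "DomainTable":
        return DomainTable([set(d) for d in self.domains])


def compute_initial_domains(pattern: LabeledGraph, target: LabeledGraph) -> DomainTable:
    """Label and degree compatibility: ``D(u) = {t : lab equal,
    in/out-degree(t) >= in/out-degree(u)}``."""
    # bucket target vertices by label to avoid the full n x n' scan
    by_label: dict[str, list[int]] = {}
    for t in range(target.n_vertices):
        by_label.setdefault(target.vertex_labels[t], []).append(t)
    domains = []
    for u in range(pattern.n_vertices):
        din, dout = pattern.in_degree(u), pattern.out_degree(u)
        domains.append(
            {
                t
                for t in by_label.get(pattern.vertex_labels[u], ())
                if target.in_degree(t) >= din and target.out_degree(t) >= dout
            }
        )
    return DomainTable(domains)


def filter_edge_compatibility(
    pattern: LabeledGraph, target: LabeledGraph, table: DomainTable
) -> DomainTable:
    """One sweep over pattern edges: for each (u, v), keep t in D(u) only
    if t has an out-neighbor in D(v), and s in D(v) only if s has an
    in-neighbor in D(u).

    Returns a new table; every domain is a subset of its input.  The
    match set is unchanged — only the search effort can shrink.
    """
    out = table.copy()
    for u, v in sorted(pattern.edges):
        du, dv = out[u], out[v]
        out.domains[u] = {t for t in du if target.out_adjacency(t) & dv}
        out.domains[v] = {s for s in dv if target.in_adjacency(s) & out.domains[u]}
    return out


def compute_domains(pattern: LabeledGraph, target: LabeledGraph) -> DomainTable:
    """Full RI-Ds preprocessing: initial domains plus the edge pass."""
    return filter_edge_compatibility(
        pattern, target, compute_initial_domains(pattern, target)
    )
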