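"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rimatch.graph import LabeledGraph, from_undirected_edges
from rimatch.matching import Mapping, MatchMode


def complete_graph(n: int, label: str = "A") -> LabeledGraph:
    return from_undirected_edges(
        f"K{n}", [label] * n, [(u, v) for u in range(n) for v in range(u + 1, n)]
    )


def path_graph(n: int, label: str = "A") -> LabeledGraph:
    return from_undirected_edges(f"P{n}", [label] * n, [(i, i + 1) for i in range(n - 1)])


def cycle_graph(n: int, label: str = "A") -> LabeledGraph:
    return from_undirected_edges(
        f"C{n}", [label] * n, [(i, (i + 1) % n) for i in range(n)]
    )


def random_labeled_digraph(
    rng: np.random.Generator, n: int, p: float, labels: list[str]
) -> LabeledGraph:
    """Arbitrary labeled digraph (not necessarily connected)."""
    edges = {
        (u, v)
        for u in range(n)
        for v in range(n)
        if u != v and rng.random() < p
    }
    vlabels = [labels[int(rng.integers(len(labels)))] for _ in range(n)]
    return LabeledGraph(f"rnd{n}", n, True, vlabels, edges)


def random_connected_digraph(
    rng: np.random.Generator, n: int, p: float, labels: list[str]
) -> LabeledGraph:
    """Connected labeled digraph: random spine plus random extra arcs."""
    edges = set()
    order = list(rng.permutation(n))
    for i in range(1, n):
        a, b = int(order[int(rng.integers(i))]), int(order[i])
        edges.add((a, b) if rng.random() < 0.5 else (b, a))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                edges.add((u, v))
    vlabels = [labels[int(rng.integers(len(labels)))] for _ in range(n)]
    return LabeledGraph(f"conn{n}", n, True, vlabels, edges)


def match_set(matches) -> set[tuple[int, ...]]:
    return {m.targets if isinstance(m, Mapping) else tuple(m) for m in matches}


def verify_mapping(
    pattern: LabeledGraph, target: LabeledGraph, m: Mapping, mode: MatchMode
) -> bool:
    """Post-hoc validity check written independently of matcher and oracle."""
    image = m.targets
    if len(set(image)) != len(image):
        return False
    for u in range(pattern.n_vertices):
        if pattern.vertex_labels[u] != target.vertex_labels[image[u]]:
            return False
    for u, v in pattern.edges:
        if not target.has_edge(image[u], image[v]):
            return False
        if mode.edge_labels_checked and pattern.edge_label(u, v) != target.edge_label(
            image[u], image[v]
        ):
            return False
    if mode.induced:
        back = {t: u for u, t in enumerate(image)}
        for tu, tv in target.edges:
            if tu in back and tv in back and not pattern.has_edge(back[tu], back[tv]):
                return False
    return True


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
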