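"""Labeled-graph data model and plain-text edge-list I/O.

Patterns and targets share one representation: a simple directed graph
(no self-loops, no parallel edges) with a mandatory label per vertex and
an optional label per edge.  Undirected graphs are stored on their
symmetric-digraph encoding — every undirected edge ``<u, v>`` becomes the
two arcs ``(u, v)`` and ``(v, u)`` — so the matcher never needs a special
case.  "Unlabeled" graphs are modeled by giving every vertex the same
label.

File format (one graph per file)::

    #<name>
    <n_vertices>
    <label of vertex 0>
    ...
    <label of vertex n-1>
    <n_edges>
    <u> <v> [<edge_label>]
    ...

Directedness is declared by the caller, not stored in the file: with
``dialect="undirected"`` each listed edge is read as a symmetric pair
(and written once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union


class GraphFormatError(ValueError):
    """Malformed graph file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class LabeledGraph:
    """A vertex-labeled simple digraph with dense 0-based vertex ids.

    Parameters
    ----------
    name:
        Identifier carried through file round-trips.
    n_vertices:
        Number of vertices; ids are ``0 .. n_vertices - 1``.
    directed:
        If ``False`` the edge set must be symmetric (the undirected
        encoding); writers then emit each symmetric pair once.
    vertex_labels:
        One label token per vertex, compared by string equality.
    edges:
        Set of ordered pairs ``(u, v)``; no self-loops or duplicates.
    edge_labels:
        Optional map from edge to label token; if given, its key set
        must equal ``edges``.
    """

    name: str
    n_vertices: int
    directed: bool
    vertex_labels: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)
    edge_labels: Optional[dict[tuple[int, int], str]] = None

    def __post_init__(self) -> None:
        self._out: list[set[int]] = [set() for _ in range(self.n_vertices)]
        self._in: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for u, v in self.edges:
            self._out[u].add(v)
            self._in[v].add(u)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.n_vertices < 0:
            raise ValueError("negative vertex count")
        if len(self.vertex_labels) != self.n_vertices:
            raise ValueError(
                f"{len(self.vertex_labels)} labels for {self.n_vertices} vertices"
            )
        for u, v in self.edges:
            if not (0 <= u < self.n_vertices and 0 <= v < self.n_vertices):
                raise ValueError(f"edge ({u}, {v}) has an out-of-range endpoint")
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
        if not self.directed:
            for u, v in self.edges:
                if (v, u) not in self.edges:
                    raise ValueError(
                        f"undirected graph missing reverse edge ({v}, {u})"
                    )
                if self.edge_labels is not None and self.edge_labels.get(
                    (u, v)
                ) != self.edge_labels.get((v, u)):
                    raise ValueError(f"asymmetric labels on undirected edge <{u}, {v}>")
        if self.edge_labels is not None and set(self.edge_labels) != self.edges:
            raise ValueError("edge_labels key set differs from edge set")

    # -- accessors --------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.edges

    def edge_label(self, u: int, v: int) -> Optional[str]:
        if self.edge_labels is None:
            return None
        return self.edge_labels.get((u, v))

    def out_adjacency(self, u: int) -> set[int]:
        self._check_vertex(u)
        return self._out[u]

    def in_adjacency(self, u: int) -> set[int]:
        self._check_vertex(u)
        return self._in[u]

    def out_degree(self, u: int) -> int:
        return len(self._out[u])

    def in_degree(self, u: int) -> int:
        return len(self._in[u])

    def neighbors(self, u: int) -> set[int]:
        """All vertices sharing an edge with ``u``, ignoring direction."""
        self._check_vertex(u)
        return self._out[u] | self._in[u]

    def degree(self, u: int) -> int:
        """Number of distinct neighbors, ignoring direction."""
        return len(self.neighbors(u))

    def _check_vertex(self, u: int) -> None:
        if not (isinstance(u, int) and 0 <= u < self.n_vertices):
            raise ValueError(f"invalid vertex id {u!r}")

    def is_connected(self) -> bool:
        """Connectivity of the direction-blind (underlying) graph."""
        if self.n_vertices == 0:
            return False
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_vertices

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        return (
            self.name == other.name
            and self.n_vertices == other.n_vertices
            and self.directed == other.directed
            and self.vertex_labels == other.vertex_labels
            and self.edges == other.edges
            and self.edge_labels == other.edge_labels
        )


# -- construction helpers ------------------------------------------------


def from_undirected_edges(
    name: str,
    vertex_labels: list[str],
    undirected_edges: Iterable[tuple[int, int]],
    edge_labels: Optional[dict[tuple[int, int], str]] = None,
) -> LabeledGraph:
    """Build the symmetric-digraph encoding of an undirected graph."""
    edges: set[tuple[int, int]] = set()
    elab: Optional[dict[tuple[int, int], str]] = {} if edge_labels is not None else None
    for u, v in undirected_edges:
        edges.add((u, v))
        edges.add((v, u))
        if elab is not None:
            lab = edge_labels[(u, v)] if (u, v) in edge_labels else edge_labels[(v, u)]
            elab[(u, v)] = lab
            elab[(v, u)] = lab
    return LabeledGraph(
        name=name,
        n_vertices=len(vertex_labels),
        directed=False,
        vertex_labels=list(vertex_labels),
        edges=edges,
        edge_labels=elab,
    )


# -- I/O ------------------------------------------------------------------


def read_graph(path_or_file: Union[str, IO[str]], dialect: str = "directed") -> LabeledGraph:
    """Parse a graph from the plain-text format.

    ``dialect`` is ``"directed"`` or ``"undirected"``; with the latter
    every listed edge ``u v`` is stored as both arcs.  Malformed input
    raises :class:`GraphFormatError` naming the line.
    """
    if dialect not in ("directed", "undirected"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(path_or_file, str):
        with open(path_or_file, encoding="utf-8") as fh:
            return read_graph(fh, dialect)
    lines = path_or_file.read().splitlines()
    pos = 0

    def next_line() -> tuple[int, str]:
        nonlocal pos
        while pos < len(lines):
            pos += 1
            text = lines[pos - 1].strip()
            if text:
                return pos, text
        raise GraphFormatError("unexpected end of file", len(lines))

    lineno, header = next_line()
    if not header.startswith("#"):
        raise GraphFormatError("expected '#<name>' header", lineno)
    name = header[1:].strip()

    lineno, text = next_line()
    try:
        n = int(text)
    except ValueError:
        raise GraphFormatError(f"expected vertex count, got {text!r}", lineno) from None
    if n < 0:
        raise GraphFormatError("negative vertex count", lineno)

    labels = []
    for _ in range(n):
        lineno, text = next_line()
        if len(text.split()) != 1:
            raise GraphFormatError(f"expected one label token, got {text!r}", lineno)
        labels.append(text)

    lineno, text = next_line()
    try:
        m = int(text)
    except ValueError:
        raise GraphFormatError(f"expected edge count, got {text!r}", lineno) from None

    edges: set[tuple[int, int]] = set()
    edge_labels: dict[tuple[int, int], str] = {}
    any_edge_label = False
    for _ in range(m):
        lineno, text = next_line()
        parts = text.split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(f"expected 'u v [label]', got {text!r}", lineno)
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise GraphFormatError(f"non-integer endpoint in {text!r}", lineno) from None
        if not (0 <= u < n and 0 <= v < n):
            raise GraphFormatError(f"endpoint out of range in edge ({u}, {v})", lineno)
        if u == v:
            raise GraphFormatError(f"self-loop at vertex {u}", lineno)
        pairs = [(u, v)] if dialect == "directed" else [(u, v), (v, u)]
        for pair in pairs:
            if pair in edges:
                raise GraphFormatError(f"duplicate edge {pair}", lineno)
            edges.add(pair)
            if len(parts) == 3:
                any_edge_label = True
                edge_labels[pair] = parts[2]
    if pos < len(lines) and any(line.strip() for line in lines[pos:]):
        raise GraphFormatError("trailing content after edge list", pos + 1)
    if any_edge_label and len(edge_labels) != len(edges):
        raise GraphFormatError("edge labels must be given for all edges or none")
    return LabeledGraph(
        name=name,
        n_vertices=n,
        directed=(dialect == "directed"),
        vertex_labels=labels,
        edges=edges,
        edge_labels=edge_labels if any_edge_label else None,
    )


def write_graph(g: LabeledGraph, path_or_file: Union[str, IO[str]]) -> None:
    """Write ``g`` so that :func:`read_graph` reproduces it exactly.

    Undirected graphs emit each symmetric edge pair once (smaller
    endpoint first).
    """
    if isinstance(path_or_file, str):
        with open(path_or_file, "w", encoding="utf-8") as fh:
            write_graph(g, fh)
        return
    fh = path_or_file
    fh.write(f"#{g.name}\n{g.n_vertices}\n")
    for lab in g.vertex_labels:
        fh.write(f"{lab}\n")
    if g.directed:
        out_edges = sorted(g.edges)
    else:
        out_edges = sorted({(min(u, v), max(u, v)) for u, v in g.edges})
    fh.write(f"{len(out_edges)}\n")
    for u, v in out_edges:
        lab = g.edge_label(u, v)
        if lab is None:
            fh.write(f"{u} {v}\n")
        else:
            fh.write(f"{u} {v} {lab}\n")
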