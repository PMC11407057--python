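"""Molecular graph container and file I/O.

A molecular graph here is a plain simple undirected graph: atoms are
vertices carrying an element label, bonds are unweighted edges.  Hydrogens
are never represented and there are no bond orders — every descriptor in
this package is a function of the 0/1 adjacency matrix alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import scipy.io
import scipy.sparse

__all__ = [
    "ELEMENTS",
    "MolecularGraph",
    "AdjacencyMatrix",
    "GraphError",
    "EdgeListParseError",
    "make_graph",
    "adjacency_of",
    "is_bipartite",
    "read_edge_list",
    "write_edge_list",
    "write_adjacency",
]

#: Element labels admitted by the two lattice families plus the generic
#: label used for reference graphs.
ELEMENTS = ("Bi", "I", "C", "X")


class GraphError(ValueError):
    """Invalid graph construction (duplicate id, bad edge, ...)."""


class EdgeListParseError(GraphError):
    """Malformed edge-list file; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class MolecularGraph:
    """Validated simple undirected graph with element labels.

    Attributes
    ----------
    elements : dict
        Maps integer vertex id to its element label.
    edges : frozenset
        Unordered distinct pairs of vertex ids, stored as sorted tuples.
    """

    elements: dict[int, str]
    edges: frozenset[tuple[int, int]]

    @property
    def vertex_ids(self) -> list[int]:
        return sorted(self.elements)

    @property
    def n_vertices(self) -> int:
        return len(self.elements)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        return sum(v in e for e in self.edges)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.elements.values():
            counts[el] = counts.get(el, 0) + 1
        return counts

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v, el in self.elements.items():
            g.add_node(v, element=el)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, element_attr: str = "element",
                      default_element: str = "X") -> "MolecularGraph":
        vertices = [(v, g.nodes[v].get(element_attr, default_element))
                    for v in g.nodes]
        return make_graph(vertices, list(g.edges))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Dense symmetric 0/1 adjacency matrix with its vertex ordering."""

    entries: np.ndarray
    vertex_order: tuple[int, ...] = field(default=())

    @property
    def order(self) -> int:
        return self.entries.shape[0]

    def __post_init__(self):
        a = np.asarray(self.entries)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphError(f"adjacency matrix must be square, got shape {a.shape}")
        if a.size and not np.array_equal(a, a.T):
            raise GraphError("adjacency matrix must be symmetric")
        if a.size and np.any(np.diag(a) != 0):
            raise GraphError("adjacency matrix must have zero diagonal")


def make_graph(vertices: list[tuple[int, str]],
               edges: list[tuple[int, int]]) -> MolecularGraph:
    """Build a validated :class:`MolecularGraph`.

    Raises :class:`GraphError` naming the offending item on duplicate ids,
    unknown element labels, self-loops, unknown endpoints or duplicate
    edges (in either orientation).
    """
    elements: dict[int, str] = {}
    for vid, el in vertices:
        vid = int(vid)
        if vid in elements:
            raise GraphError(f"duplicate vertex id {vid}")
        if el not in ELEMENTS:
            raise GraphError(
                f"unknown element {el!r} for vertex {vid}; expected one of {ELEMENTS}")
        elements[vid] = el

    edge_set: set[tuple[int, int]] = set()
    for u, v in edges:
        u, v = int(u), int(v)
        if u == v:
            raise GraphError(f"self-loop at vertex {u}")
        for w in (u, v):
            if w not in elements:
                raise GraphError(f"edge ({u}, {v}) references undeclared vertex {w}")
        key = (u, v) if u < v else (v, u)
        if key in edge_set:
            raise GraphError(f"duplicate edge ({u}, {v})")
        edge_set.add(key)
    return MolecularGraph(elements=elements, edges=frozenset(edge_set))


def adjacency_of(g: MolecularGraph,
                 ordering: list[int] | None = None) -> AdjacencyMatrix:
    """0/1 adjacency matrix of ``g`` under ``ordering`` (default: ascending id).

    The ordering affects only the matrix presentation; every descriptor
    computed downstream is spectral and hence permutation-invariant.
    """
    if ordering is None:
        ordering = g.vertex_ids
    else:
        if sorted(ordering) != g.vertex_ids:
            raise GraphError("ordering must be a permutation of the vertex ids")
    index = {v: i for i, v in enumerate(ordering)}
    a = np.zeros((g.n_vertices, g.n_vertices), dtype=np.int8)
    for u, v in g.edges:
        a[index[u], index[v]] = 1
        a[index[v], index[u]] = 1
    return AdjacencyMatrix(entries=a, vertex_order=tuple(ordering))


def is_bipartite(g: MolecularGraph) -> tuple[bool, tuple[set[int], set[int]] | None]:
    """Test 2-colourability; return the colour classes when they exist."""
    nxg = g.to_networkx()
    if g.n_vertices == 0:
        return True, (set(), set())
    if not nx.is_bipartite(nxg):
        return False, None
    left: set[int] = set()
    right: set[int] = set()
    for comp in nx.connected_components(nxg):
        a, b = nx.bipartite.sets(nxg.subgraph(comp))
        left |= a
        right |= b
    return True, (left, right)


# ---------------------------------------------------------------------------
# Edge-list dialect: tab-separated, "#" comments, an optional vertex block of
# "V <id> <element>" lines followed by "<id> <id>" edge lines.  Vertices that
# appear only in edges default to element "X".
# ---------------------------------------------------------------------------

def write_edge_list(g: MolecularGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# latspec edge list\n")
        fh.write("# V <id> <element> | <id> <id>\n")
        for v in g.vertex_ids:
            fh.write(f"V\t{v}\t{g.elements[v]}\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> MolecularGraph:
    path = Path(path)
    vertices: list[tuple[int, str]] = []
    edges: list[tuple[int, int]] = []
    declared: set[int] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "V":
                if len(fields) != 3:
                    raise EdgeListParseError(
                        f"vertex line needs 3 fields, got {len(fields)}", lineno)
                try:
                    vid = int(fields[1])
                except ValueError:
                    raise EdgeListParseError(
                        f"non-integer vertex id {fields[1]!r}", lineno) from None
                vertices.append((vid, fields[2]))
                declared.add(vid)
            else:
                if len(fields) != 2:
                    raise EdgeListParseError(
                        f"edge line needs 2 fields, got {len(fields)}", lineno)
                try:
                    u, v = int(fields[0]), int(fields[1])
                except ValueError:
                    raise EdgeListParseError(
                        f"non-integer vertex id in {fields!r}", lineno) from None
                edges.append((u, v))
    # vertices appearing only in edges get the generic label
    for u, v in edges:
        for w in (u, v):
            if w not in declared:
                vertices.append((w, "X"))
                declared.add(w)
    return make_graph(vertices, edges)


def write_adjacency(g: MolecularGraph, path: str | Path,
                    format: str = "matrix-market") -> None:
    """Write the adjacency matrix as Matrix Market pattern or dense CSV.

    Matrix Market output uses the coordinate symmetric pattern format with
    1-based indices (lower triangle); CSV writes the dense 0/1 matrix, one
    row per line.
    """
    path = Path(path)
    a = adjacency_of(g).entries
    if format == "matrix-market":
        sparse = scipy.sparse.coo_matrix(a)
        with path.open("wb") as fh:  # stream keeps mmwrite from appending .mtx
            scipy.io.mmwrite(fh, sparse, field="pattern", symmetry="symmetric")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            for row in a:
                writer.writerow([int(x) for x in row])
    else:
        raise GraphError(
            f"unknown adjacency format {format!r}; supported: matrix-market, csv")
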