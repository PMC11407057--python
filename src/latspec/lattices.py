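"""Parametric generators for the two molecular lattice families.

Two families are built in:

``bii3`` — a single BiI3 sheet fragment.  Bismuth atoms form a backbone
(zigzag hexagonal tube of ``m + 2`` hexagons around, ``n`` rings tall,
closed off by a small capping ring); every backbone contact is realised
by a pair of bridging iodines (edge-sharing BiI6 octahedra) and each Bi
is topped up to its full valence of six with terminal iodines.  The
resulting bond graph is bipartite Bi/I, so its spectrum is symmetric
about zero and the signature vanishes; the large iodine excess produces
the family's characteristic nullity growth.

``bre`` — an all-carbon benzene network on a P-type (schwarzite-like)
surface patch: ``n`` strips of ``6 m`` linearly fused hexagons, adjacent
strips joined by widely spaced vertical bonds so that the connector
rings between strips are even (10-membered), plus a small boundary
decoration of pendant carbons.  Every carbon is sp2 (degree at most 3)
and all cycles are even, so the spectrum is again symmetric.

Both generators are deterministic and driven by an explicit
:class:`TilingRules` record, so a corrected reconstruction of either
family is a data change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import networkx as nx
import yaml

from .graph import MolecularGraph, GraphError, make_graph

__all__ = [
    "LatticeIndex",
    "TilingRules",
    "CountRecord",
    "BII3_RULES",
    "BRE_RULES",
    "bii3_sheet",
    "benzene_ptype",
    "reference_graph",
    "expected_counts",
    "STRUCTURES",
    "REFERENCE_FAMILIES",
]

STRUCTURES = ("bii3", "bre")
REFERENCE_FAMILIES = ("path", "cycle", "star", "complete", "empty")


@dataclass(frozen=True)
class LatticeIndex:
    """Unit-cell repeat counts: ``m`` horizontal, ``n`` vertical."""

    m: int
    n: int

    def __post_init__(self):
        if int(self.m) != self.m or int(self.n) != self.n:
            raise GraphError(f"lattice indices must be integers, got ({self.m}, {self.n})")
        if self.m < 1 or self.n < 1:
            raise GraphError(f"lattice indices must be >= 1, got ({self.m}, {self.n})")


@dataclass(frozen=True)
class TilingRules:
    """Data description of a builtin lattice construction.

    BiI3 knobs
    ----------
    ring_circumference_offset
        Backbone tube circumference in hexagons is ``m + offset``.
    cap_size, cap_chord, cap_links
        Size of the capping ring, whether it carries a chord, and how many
        link bonds tie it to the top rim.
    bridge_multiplicity
        Bridging iodines per backbone contact (2 = edge-sharing octahedra).
    metal_valence
        Iodine neighbours per Bi; the shortfall is filled with terminal I.

    BRE knobs
    ---------
    hexagons_per_m
        Fused hexagons per strip and horizontal unit cell.
    bond_spacing, bond_offset
        Inter-strip bonds sit at top-path positions ``offset, offset+spacing,
        ...``; spacing 4 yields 10-membered (even) connector rings.
    pendant_positions, chain_start, chain_spacing
        Boundary decoration: two single pendant atoms on like-coloured
        sites (forcing a colour-class imbalance of 2, hence nullity 2) and
        ``m - 1`` two-atom chains.
    """

    family: str = "bii3"
    # BiI3
    ring_circumference_offset: int = 2
    cap_size: int = 6
    cap_chord: bool = True
    cap_links: int = 3
    bridge_multiplicity: int = 2
    metal_valence: int = 6
    # BRE
    hexagons_per_m: int = 6
    bond_spacing: int = 4
    bond_offset: int = 1
    pendant_positions: tuple[int, int] = (1, 5)
    chain_start: int = 9
    chain_spacing: int = 4

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "TilingRules":
        data = yaml.safe_load(Path(path).read_text())
        data["pendant_positions"] = tuple(data.get("pendant_positions", (1, 5)))
        return cls(**data)


BII3_RULES = TilingRules(family="bii3")
BRE_RULES = TilingRules(family="bre")


@dataclass(frozen=True)
class CountRecord:
    """Vertex census of a lattice graph plus tabulated expectations.

    ``expected_p`` / ``expected_eta`` are the positive-inertia and nullity
    values the m = 3 columns of the two families are calibrated against;
    they are ``None`` where no tabulated sequence constrains the family.
    """

    total_vertices: int
    count_per_element: dict[str, int]
    expected_p: int | None
    expected_eta: int | None


def _relabel(nxg: nx.Graph) -> MolecularGraph:
    """Deterministic integer relabelling (sorted node keys, ids from 1)."""
    order = sorted(nxg.nodes, key=lambda k: (str(type(k)), str(k)))
    mapping = {node: i + 1 for i, node in enumerate(order)}
    vertices = [(mapping[v], nxg.nodes[v]["element"]) for v in order]
    edges = [(mapping[u], mapping[v]) for u, v in nxg.edges]
    return make_graph(vertices, edges)


def _bii3_backbone(idx: LatticeIndex, rules: TilingRules) -> nx.Graph:
    c = idx.m + rules.ring_circumference_offset
    h = nx.Graph()
    # n zigzag rings, each a 2c-cycle; atoms keyed (ring, position)
    for t in range(idx.n):
        for i in range(2 * c):
            h.add_edge(("r", t, i), ("r", t, (i + 1) % (2 * c)))
    # inter-ring bonds: odd positions bond down to the even position below
    for t in range(idx.n - 1):
        for j in range(c):
            h.add_edge(("r", t, 2 * j + 1), ("r", t + 1, 2 * j))
    # capping ring with one chord, tied to deg-2 rim sites of ring 0
    k = rules.cap_size
    for i in range(k):
        h.add_edge(("cap", i), ("cap", (i + 1) % k))
    if rules.cap_chord:
        h.add_edge(("cap", 0), ("cap", 2))
    for link in range(rules.cap_links):
        h.add_edge(("cap", k - 1 - link), ("r", 0, 2 * link))
    return h


def bii3_sheet(idx: LatticeIndex | tuple[int, int],
               rules: TilingRules = BII3_RULES) -> MolecularGraph:
    """BiI3 sheet fragment with ``m`` x ``n`` unit cells.

    The graph is bipartite with parts {Bi}, {I} by construction (every
    bond joins a bismuth to an iodine), connected, and deterministic for
    fixed arguments.
    """
    if not isinstance(idx, LatticeIndex):
        idx = LatticeIndex(*idx)
    backbone = _bii3_backbone(idx, rules)
    g = nx.Graph()
    for node in backbone.nodes:
        g.add_node(("Bi", node), element="Bi")
    counter = 0
    for u, v in backbone.edges:
        for _ in range(rules.bridge_multiplicity):
            iod = ("I", counter)
            counter += 1
            g.add_node(iod, element="I")
            g.add_edge(("Bi", u), iod)
            g.add_edge(("Bi", v), iod)
    for node in backbone.nodes:
        missing = rules.metal_valence - rules.bridge_multiplicity * backbone.degree[node]
        if missing < 0:
            raise GraphError(
                f"tiling rules overload Bi site {node}: backbone degree "
                f"{backbone.degree[node]} exceeds valence {rules.metal_valence}")
        for _ in range(missing):
            iod = ("I", counter)
            counter += 1
            g.add_node(iod, element="I")
            g.add_edge(("Bi", node), iod)
    return _relabel(g)


def benzene_ptype(idx: LatticeIndex | tuple[int, int],
                  rules: TilingRules = BRE_RULES) -> MolecularGraph:
    """Benzene-ring network on a P-type surface patch, ``m`` x ``n`` cells.

    All-carbon, connected, maximum degree 3 (sp2), all cycles even.
    """
    if not isinstance(idx, LatticeIndex):
        idx = LatticeIndex(*idx)
    p = rules.hexagons_per_m * idx.m
    g = nx.Graph()
    # strips of p fused hexagons: zigzag top/bottom paths with verticals
    for s in range(idx.n):
        for j in range(2 * p):
            g.add_edge(("t", s, j), ("t", s, j + 1))
            g.add_edge(("b", s, j), ("b", s, j + 1))
        for j in range(0, 2 * p + 1, 2):
            g.add_edge(("t", s, j), ("b", s, j))
    # inter-strip bonds (bottom of strip s to top of strip s+1); strip 0's
    # top path stays free for the boundary decoration
    n_bonds = rules.hexagons_per_m // 2 * idx.m
    for s in range(idx.n - 1):
        for b in range(n_bonds):
            j = rules.bond_offset + rules.bond_spacing * b
            g.add_edge(("b", s, j), ("t", s + 1, j))
    # boundary decoration: 2 single pendants + (m - 1) two-atom chains
    for i, j in enumerate(rules.pendant_positions):
        g.add_edge(("t", 0, j), ("p", i))
    for i in range(idx.m - 1):
        j = rules.chain_start + rules.chain_spacing * i
        g.add_edge(("t", 0, j), ("q", i, 0))
        g.add_edge(("q", i, 0), ("q", i, 1))
    nx.set_node_attributes(g, "C", "element")
    return _relabel(g)


def reference_graph(family: str, k: int) -> MolecularGraph:
    """Standard graph with a closed-form spectrum (element label X).

    path P_k, cycle C_k (k >= 3), star K_{1,k-1}, complete K_k, or the
    edgeless graph on k vertices.
    """
    if family not in REFERENCE_FAMILIES:
        raise GraphError(
            f"unknown reference family {family!r}; expected one of {REFERENCE_FAMILIES}")
    if k < 1 or (family == "cycle" and k < 3) or (family == "star" and k < 2):
        raise GraphError(f"vertex count {k} out of range for family {family!r}")
    builders = {
        "path": nx.path_graph,
        "cycle": nx.cycle_graph,
        "star": lambda q: nx.star_graph(q - 1),
        "complete": nx.complete_graph,
        "empty": nx.empty_graph,
    }
    nxg = builders[family](k)
    nx.set_node_attributes(nxg, "X", "element")
    return _relabel(nxg)


def expected_counts(structure: str, idx: LatticeIndex | tuple[int, int],
                    parsing: str = "default") -> CountRecord:
    """Vertex census plus the tabulated m = 3 calibration expectations.

    The BiI3 nullity column admits two readings of the run-together
    digits; ``parsing="default"`` adopts eta = 20n + 20 (consistent with
    eta = |I| - |Bi| under a full-rank biadjacency and near 1:3 Bi:I
    stoichiometry), ``parsing="compact"`` the alternate eta = 2n + 2.
    Only m = 3 is tabulated; for other m the expectations are ``None``.
    """
    if structure not in STRUCTURES:
        raise GraphError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")
    if parsing not in ("default", "compact"):
        raise GraphError(f"unknown parsing {parsing!r}; expected default or compact")
    if not isinstance(idx, LatticeIndex):
        idx = LatticeIndex(*idx)
    g = bii3_sheet(idx) if structure == "bii3" else benzene_ptype(idx)
    expected_p = expected_eta = None
    if idx.m == 3:
        if structure == "bii3":
            expected_p = 10 * idx.n + 6
            expected_eta = (20 * idx.n + 20) if parsing == "default" else (2 * idx.n + 2)
        else:
            expected_p = 37 * idx.n + 2
            expected_eta = 2
    return CountRecord(
        total_vertices=g.n_vertices,
        count_per_element=g.element_counts(),
        expected_p=expected_p,
        expected_eta=expected_eta,
    )
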