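"""Ring geometry and shape classification of antibody/receptor assemblies.

A bivalent IgG whose two Fab arms each engage one protomer of a receptor
homodimer can daisy-chain preformed dimers.  Whether the chain closes into a
regular polygon is a hinge-geometry question: the angle between the two Fab
arms must accommodate the interior vertex angle 180·(n−2)/n of the n-gon,
and the epitope-to-epitope span of the receptor dimer must match the reach
between the two paratopes.  Electron-microscopy particles of such complexes
are classified into six shape categories — linear, <tetragonal, tetragonal,
pentagonal, hexagonal, >hexagonal — and summarised as category proportions
with the total polygonal (closed-ring, ≥4 hubs) fraction.

Assemblies are bipartite graphs: ``igg_hub`` nodes (an IgG, degree ≤ 2: two
Fab arms) and ``receptor_dimer`` nodes (degree ≤ 2: two epitopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "CATEGORIES",
    "GeometryParams",
    "CategoryCounts",
    "make_assembly_graph",
    "polygon_vertex_angle",
    "ring_feasibility",
    "classify_assembly",
    "category_proportions",
]

CATEGORIES = ("linear", "lt_tetragonal", "tetragonal", "pentagonal",
              "hexagonal", "gt_hexagonal")

POLYGONAL = frozenset({"tetragonal", "pentagonal", "hexagonal", "gt_hexagonal"})


@dataclass(frozen=True)
class GeometryParams:
    """Geometric inputs of the ring-feasibility argument.

    fab_fab_angle_range : allowed angle between the two Fab arms of one IgG,
        degrees (IgG1 hinge range 115–148°).
    edge_span : receptor-dimer epitope-to-epitope distance, Å (~120).
    paratope_reach : optimal distance between an IgG's two paratopes, Å (~130).
    vertex_tolerance : degrees of slack absorbing Fab elbow flexibility, the
        ~15° epitope tilt, out-of-plane pucker and non-regular rings.
    span_slack : Å of tolerated |edge_span − paratope_reach| mismatch.
    """

    fab_fab_angle_range: tuple[float, float] = (115.0, 148.0)
    edge_span: float = 120.0
    paratope_reach: float = 130.0
    vertex_tolerance: float = 25.0
    span_slack: float = 20.0

    def __post_init__(self):
        lo, hi = self.fab_fab_angle_range
        if lo > hi:
            raise ValueError("angle range low > high")
        if self.edge_span <= 0 or self.paratope_reach <= 0:
            raise ValueError("spans must be positive")

    def edge_admissible(self) -> bool:
        return abs(self.edge_span - self.paratope_reach) <= self.span_slack


def polygon_vertex_angle(n: int) -> float:
    """Interior vertex angle of a regular n-gon: 180·(n−2)/n degrees."""
    if n < 3:
        raise ValueError("a polygon needs n >= 3 vertices")
    return 180.0 * (n - 2) / n


def ring_feasibility(params: GeometryParams,
                     n_range: list[int]) -> dict[int, dict]:
    """Which closed n-gon rings the hinge geometry admits.

    ``n`` is feasible iff the regular n-gon vertex angle lies inside the
    Fab–Fab angle range widened by ±vertex_tolerance.  The margin is the
    distance (degrees) to the nearest widened bound: positive inside,
    negative outside.  Narrowing the angle range or tolerance never adds a
    feasible n.
    """
    if not n_range:
        raise ValueError("empty n range")
    lo, hi = params.fab_fab_angle_range
    lo -= params.vertex_tolerance
    hi += params.vertex_tolerance
    out = {}
    for n in n_range:
        angle = polygon_vertex_angle(n)
        margin = min(angle - lo, hi - angle)
        out[n] = {"feasible": margin >= 0, "margin": margin, "vertex_angle": angle}
    return out


def make_assembly_graph(edges: list[tuple[str, str]]) -> nx.Graph:
    """Build and validate a hub/dimer graph from (hub_id, dimer_id) edges.

    Node names carry their type implicitly through edge position; explicit
    ``kind`` attributes are set (``igg_hub`` / ``receptor_dimer``).
    """
    g = nx.Graph()
    for hub, dimer in edges:
        g.add_node(hub, kind="igg_hub")
        g.add_node(dimer, kind="receptor_dimer")
        g.add_edge(hub, dimer)
    _validate(g)
    return g


def _validate(graph: nx.Graph):
    for node, data in graph.nodes(data=True):
        kind = data.get("kind")
        if kind not in ("igg_hub", "receptor_dimer"):
            raise ValueError(f"node {node!r} lacks a valid kind attribute")
        if graph.degree(node) > 2:
            raise ValueError(
                f"node {node!r} has degree {graph.degree(node)} > 2 "
                "(two Fabs per IgG, two epitopes per dimer)")
    for u, v in graph.edges:
        if graph.nodes[u]["kind"] == graph.nodes[v]["kind"]:
            raise ValueError(f"edge {u!r}–{v!r} is not hub–dimer: graph not bipartite")


def classify_assembly(graph: nx.Graph) -> str:
    """Shape category of one connected assembly.

    A single closed cycle with k IgG hubs maps to lt_tetragonal (k ≤ 3),
    tetragonal (4), pentagonal (5), hexagonal (6) or gt_hexagonal (k ≥ 7);
    any acyclic connected graph is linear.  Disconnected input is an error —
    classify components separately.
    """
    _validate(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("disconnected graph: classify components separately")
    cycles = nx.cycle_basis(graph)
    if not cycles:
        return "linear"
    # With all degrees <= 2 a connected graph has at most one cycle and the
    # cycle covers every node.
    hubs = sum(1 for n in cycles[0] if graph.nodes[n]["kind"] == "igg_hub")
    if hubs <= 3:
        return "lt_tetragonal"
    if hubs == 4:
        return "tetragonal"
    if hubs == 5:
        return "pentagonal"
    if hubs == 6:
        return "hexagonal"
    return "gt_hexagonal"


@dataclass
class CategoryCounts:
    counts: dict[str, int]
    total: int
    proportions: dict[str, float] = field(default_factory=dict)  # %, 1 decimal
    polygonal_fraction: float = 0.0  # %, 1 decimal

    def to_dict(self) -> dict:
        return {"counts": self.counts, "total": self.total,
                "proportions": self.proportions,
                "polygonal_fraction": self.polygonal_fraction}


def category_proportions(labels: list[str]) -> CategoryCounts:
    """Exact counts and percentage proportions of shape categories.

    The polygonal fraction pools the closed-ring categories tetragonal
    through >hexagonal and is computed from raw counts before rounding.
    """
    if not labels:
        raise ValueError("empty label list")
    counts = {c: 0 for c in CATEGORIES}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown category {lab!r}")
        counts[lab] += 1
    total = len(labels)
    proportions = {c: round(100.0 * counts[c] / total, 1) for c in CATEGORIES}
    polygonal = sum(counts[c] for c in POLYGONAL)
    return CategoryCounts(counts, total, proportions,
                          round(100.0 * polygonal / total, 1))
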