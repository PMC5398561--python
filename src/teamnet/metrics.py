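"""Whole-network metric panel and per-vertex summaries for teaming networks.

The panel bundles the structural measures used to compare construction
algorithms side by side: edge/vertex counts, diameter d on the largest
component, degree assortativity r, reciprocity ρ, global clustering
(transitivity) C, density D, largest-component size lco, degree and
edge-weight extremes, and the self-loop fractions E_loop/E and V_loop/V.

Conventions (documented because the literature varies):

* Self-loops are excluded from degree, density, clustering, assortativity
  and betweenness; they are reported only through the loop fractions.
* Density is ``d·m / (n(n-1))`` with d=1 for directed and d=2 for
  undirected graphs, m the number of non-loop edges.
* Assortativity and clustering are evaluated on the undirected simple
  skeleton (the printed degree-assortativity formula is undirected).
* Reciprocity is the fraction of directed non-loop edges whose reverse
  is present; it is trivially 1 for undirected networks.
* Diameter is the longest shortest geodesic within the largest (weakly,
  for directed graphs) connected component, excluding unreachable pairs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np

from .network_builders import TeamingNetwork

__all__ = [
    "DegreeSequence",
    "MetricsPanel",
    "compute_metric_panel",
    "degree_distribution",
    "normalized_betweenness",
    "panel_table",
]


@dataclass
class MetricsPanel:
    edge_count: int
    vertex_count: int
    diameter: int
    assortativity: float
    reciprocity: float
    global_clustering: float
    density: float
    lco: int
    max_degree: int
    mean_degree: float
    max_edge_weight: int
    mean_edge_weight: float
    loop_edge_fraction: float
    loop_vertex_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def _simple_graphs(network: TeamingNetwork):
    """(graph-with-loops, loop-free graph, undirected loop-free skeleton)."""
    G = network.to_networkx()
    Gs = G.copy()
    Gs.remove_edges_from(nx.selfloop_edges(Gs))
    skel = Gs.to_undirected() if network.directed else Gs
    return G, Gs, skel


def _diameter(Gs, directed: bool) -> int:
    if Gs.number_of_nodes() == 0:
        return 0
    if directed:
        comp = max(nx.weakly_connected_components(Gs), key=len)
    else:
        comp = max(nx.connected_components(Gs), key=len)
    H = Gs.subgraph(comp)
    best = 0
    for source in H:
        lengths = nx.single_source_shortest_path_length(H, source)
        if lengths:
            best = max(best, max(lengths.values()))
    return int(best)


def compute_metric_panel(network: TeamingNetwork) -> MetricsPanel:
    """Compute the full comparison panel for one network."""
    if network.n_vertices == 0:
        raise ValueError("no vertices")
    G, Gs, skel = _simple_graphs(network)
    n = G.number_of_nodes()
    m = Gs.number_of_edges()  # non-loop edges
    e_total = network.n_edges

    d_factor = 1 if network.directed else 2
    density = d_factor * m / (n * (n - 1)) if n > 1 else 0.0

    if network.directed:
        recip_edges = sum(1 for u, v in Gs.edges if Gs.has_edge(v, u))
        reciprocity = recip_edges / m if m else 0.0
    else:
        reciprocity = 1.0

    degrees = dict(skel.degree())
    deg_vals = np.array(list(degrees.values())) if degrees else np.array([0])

    if m and len({d for d in degrees.values()}) > 1:
        assort = float(nx.degree_assortativity_coefficient(skel))
    else:
        assort = float("nan")  # degenerate: degree variance is zero

    weights = np.array(
        [network.weight(u, v) for (u, v) in network.edges], dtype=float
    )
    if weights.size == 0:
        weights = np.array([0.0])

    comps = (
        nx.weakly_connected_components(G) if network.directed else nx.connected_components(G)
    )
    lco = max((len(c) for c in comps), default=0)

    return MetricsPanel(
        edge_count=e_total,
        vertex_count=n,
        diameter=_diameter(Gs, network.directed),
        assortativity=assort,
        reciprocity=reciprocity,
        global_clustering=float(nx.transitivity(skel)) if skel.number_of_nodes() else 0.0,
        density=float(density),
        lco=int(lco),
        max_degree=int(deg_vals.max()),
        mean_degree=float(deg_vals.mean()),
        max_edge_weight=int(weights.max()),
        mean_edge_weight=float(weights.mean()),
        loop_edge_fraction=network.loop_edge_count / e_total if e_total else 0.0,
        loop_vertex_fraction=network.loop_vertex_count / n if n else 0.0,
    )


def normalized_betweenness(network: TeamingNetwork) -> dict[str, float]:
    """Normalized betweenness centrality C'β per vertex.

    Raw betweenness (shortest-path counts through each vertex, endpoints
    excluded) is divided by (N-1)(N-2) for directed networks and by
    (N-1)(N-2)/2 for undirected ones, bounding values to [0, 1].
    Self-loops are ignored.
    """
    _, Gs, _ = _simple_graphs(network)
    N = Gs.number_of_nodes()
    if N < 3:
        raise ValueError("normalized betweenness undefined for fewer than 3 vertices")
    return {v: float(b) for v, b in nx.betweenness_centrality(Gs, normalized=True).items()}


@dataclass
class DegreeSequence:
    """Per-vertex degrees with rescaled values and the empirical P(k)."""

    vertices: list[str]
    degrees: np.ndarray
    rescale: bool = False

    @property
    def k_max(self) -> int:
        return int(self.degrees.max()) if self.degrees.size else 0

    @property
    def rescaled(self) -> np.ndarray:
        kmax = self.k_max
        return self.degrees / kmax if kmax else self.degrees.astype(float)

    @property
    def values(self) -> np.ndarray:
        return self.rescaled if self.rescale else self.degrees

    def pk(self) -> dict[int, float]:
        """Empirical degree distribution P(k) by frequency."""
        if self.degrees.size == 0:
            return {}
        ks, counts = np.unique(self.degrees, return_counts=True)
        total = counts.sum()
        return {int(k): float(c / total) for k, c in zip(ks, counts)}


def degree_distribution(network: TeamingNetwork, rescale: bool = False) -> DegreeSequence:
    """Degrees ignoring self-loops (total in+out degree for directed graphs)."""
    if network.n_vertices == 0:
        raise ValueError("no vertices")
    _, Gs, _ = _simple_graphs(network)
    verts = sorted(network.vertices)
    degs = np.array(
        [Gs.degree(v) if v in Gs else 0 for v in verts], dtype=int
    )
    return DegreeSequence(vertices=verts, degrees=degs, rescale=rescale)


def panel_table(panels: dict[str, MetricsPanel]) -> str:
    """Render panels side by side as a fixed-width text table."""
    rows = [
        ("Edges (E)", "edge_count", "{:d}"),
        ("Vertices (V)", "vertex_count", "{:d}"),
        ("E_loop/E", "loop_edge_fraction", "{:.3f}"),
        ("V_loop/V", "loop_vertex_fraction", "{:.3f}"),
        ("d", "diameter", "{:d}"),
        ("r", "assortativity", "{:.5f}"),
        ("rho", "reciprocity", "{:.5f}"),
        ("C", "global_clustering", "{:.5f}"),
        ("D", "density", "{:.5f}"),
        ("lco", "lco", "{:d}"),
        ("Max. V degree", "max_degree", "{:d}"),
        ("Mean V deg.", "mean_degree", "{:.3f}"),
        ("Max. E weight", "max_edge_weight", "{:d}"),
        ("Mean E weight", "mean_edge_weight", "{:.3f}"),
    ]
    names = list(panels)
    width = max(14, *(len(n) + 2 for n in names))
    out = ["Metric".ljust(18) + "".join(n.rjust(width) for n in names)]
    for label, attr, fmt in rows:
        cells = []
        for n in names:
            val = getattr(panels[n], attr)
            try:
                cells.append(fmt.format(val).rjust(width))
            except (ValueError, TypeError):
                cells.append(str(val).rjust(width))
        out.append(label.ljust(18) + "".join(cells))
    return "\n".join(out)
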