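"""Community detection and geospatial edge binning for teaming networks.

Communities are found with the divisive Girvan–Newman procedure: edges
with the highest edge-betweenness are removed one at a time, and the
partition (into connected components) maximizing Newman modularity along
the removal sequence is returned.  The algorithm runs on the undirected,
unweighted skeleton of the network — optionally restricted to edges
whose two endpoints both geocode to a given state, mirroring the usual
state-level restriction that keeps the O(m²n) cost tractable.  Ties in
edge betweenness are broken by removing the lexicographically smallest
(u, v) pair, making the output deterministic.

Geospatial binning assigns each edge a great-circle (haversine) length
in miles between its endpoint coordinates and tallies edges into
contiguous distance bins (default 16, from "<= 1 mile" up to
"2000–4000 miles"), with self-loops counted at distance zero and edges
with ungeocodable endpoints routed to a separate bucket rather than
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .claims_io import ProviderRegistry
from .network_builders import TeamingNetwork

__all__ = [
    "CommunityPartition",
    "DEFAULT_BIN_EDGES_MILES",
    "EARTH_RADIUS_MILES",
    "EdgeDistanceBin",
    "detect_communities",
    "edge_distance_bins",
    "girvan_newman_partition",
    "haversine_miles",
    "rand_index",
]

EARTH_RADIUS_MILES = 3958.8

#: 16 contiguous mile ranges extending the canonical set
#: (<=1, 20-40, 100-200, 800-1000, 2000-4000) to full coverage.
DEFAULT_BIN_EDGES_MILES = (
    0.0, 1.0, 2.0, 4.0, 10.0, 20.0, 40.0, 60.0, 100.0, 200.0,
    400.0, 600.0, 800.0, 1000.0, 1500.0, 2000.0, 4000.0,
)


@dataclass
class CommunityPartition:
    """A hard partition of vertices: every vertex in exactly one community."""

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    @property
    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for c in self.membership.values():
            counts[c] = counts.get(c, 0) + 1
        return sorted(counts.values(), reverse=True)

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for v, c in self.membership.items():
            groups.setdefault(c, set()).add(v)
        return sorted(groups.values(), key=lambda s: (-len(s), min(s)))


def _components_partition(G) -> list[set]:
    return [set(c) for c in nx.connected_components(G)]


def girvan_newman_partition(G: nx.Graph, use_weights: bool = False) -> CommunityPartition:
    """Run Girvan–Newman on an undirected simple graph, returning the
    modularity-maximizing partition along the edge-removal dendrogram.

    Deterministic: among edges sharing the maximal betweenness the
    lexicographically smallest sorted (u, v) pair is removed first.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    original = G.copy()
    work = G.copy()
    weight = "weight" if use_weights else None

    best_parts = _components_partition(work)
    best_q = nx.algorithms.community.modularity(original, best_parts)

    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, weight=weight)
        max_b = max(eb.values())
        target = min(
            tuple(sorted(e)) for e, b in eb.items() if abs(b - max_b) < 1e-12
        )
        work.remove_edge(*target)
        parts = _components_partition(work)
        q = nx.algorithms.community.modularity(original, parts)
        if q > best_q + 1e-12:
            best_q = q
            best_parts = parts

    membership: dict[str, int] = {}
    for cid, part in enumerate(sorted(best_parts, key=lambda s: (-len(s), min(s)))):
        for v in part:
            membership[v] = cid
    return CommunityPartition(membership=membership, modularity=float(best_q))


def detect_communities(
    network: TeamingNetwork,
    state_filter: str | None = None,
    registry: ProviderRegistry | None = None,
    *,
    max_edges: int = 5000,
    use_weights: bool = False,
) -> CommunityPartition:
    """Girvan–Newman communities on the (optionally state-filtered) network.

    The network is reduced to its undirected, loop-free skeleton.  With a
    ``state_filter``, only edges whose *both* endpoints geocode to that
    state survive; a registry covering the filtered vertices is then
    required.  Networks above ``max_edges`` are refused — restrict to a
    state first — because edge betweenness is recomputed after every
    removal (O(m²n)).
    """
    G = network.to_networkx().to_undirected() if network.directed else network.to_networkx()
    G.remove_edges_from(nx.selfloop_edges(G))
    if state_filter is not None:
        if registry is None:
            raise ValueError("state filtering requires a provider registry")
        keep = [
            (u, v)
            for u, v in G.edges
            if registry.state(u) == state_filter and registry.state(v) == state_filter
        ]
        G = G.edge_subgraph(keep).copy()
    if G.number_of_nodes() == 0:
        raise ValueError("no vertices after filtering")
    if G.number_of_edges() > max_edges:
        raise ValueError(
            f"network has {G.number_of_edges()} edges (> {max_edges}); "
            "apply a state filter or censor before community detection"
        )
    return girvan_newman_partition(G, use_weights=use_weights)


def rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Rand index between two labelings over the same vertex set.

    Pair-counting definition: the fraction of vertex pairs on whose
    togetherness the two partitions agree.
    """
    keys = sorted(labels_a)
    if sorted(labels_b) != keys:
        raise ValueError("labelings cover different vertex sets")
    if len(keys) < 2:
        return 1.0
    agree = 0
    total = 0
    for x, y in combinations(keys, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total


def haversine_miles(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in miles (Earth radius 3958.8 mi)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


@dataclass
class EdgeDistanceBin:
    """Edges whose endpoint separation falls in [lower, upper) miles."""

    label: str
    lower: float
    upper: float
    count: int = 0
    edges: list[tuple[str, str]] = field(default_factory=list)
    loop_count: int = 0


def edge_distance_bins(
    network: TeamingNetwork,
    registry: ProviderRegistry,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES_MILES,
) -> tuple[list[EdgeDistanceBin], list[tuple[str, str]]]:
    """Assign every edge to a great-circle distance bin.

    Returns ``(bins, ungeocodable)`` where the final bin is open-ended
    and *ungeocodable* lists edges with a missing endpoint coordinate
    (reported, never silently dropped).  Self-loops land in the zero-
    distance bin and are additionally tallied in its ``loop_count``.
    """
    if len(bin_edges) < 2 or any(
        b2 <= b1 for b1, b2 in zip(bin_edges, bin_edges[1:])
    ):
        raise ValueError("bin_edges must be strictly increasing")
    bins = [
        EdgeDistanceBin(
            label=(f"<= {hi:g} mi" if lo == 0 else f"{lo:g}-{hi:g} mi"),
            lower=lo,
            upper=hi,
        )
        for lo, hi in zip(bin_edges, bin_edges[1:])
    ]
    bins.append(EdgeDistanceBin(label=f"> {bin_edges[-1]:g} mi", lower=bin_edges[-1],
                                upper=float("inf")))
    boundaries = np.asarray(bin_edges[1:])
    ungeocodable: list[tuple[str, str]] = []
    for (u, v) in sorted(network.edges):
        if u == v:
            bins[0].count += 1
            bins[0].loop_count += 1
            bins[0].edges.append((u, v))
            continue
        cu, cv = registry.coords(u), registry.coords(v)
        if cu is None or cv is None:
            ungeocodable.append((u, v))
            continue
        dist = haversine_miles(cu[0], cu[1], cv[0], cv[1])
        idx = int(np.searchsorted(boundaries, dist, side="left"))
        bins[idx].count += 1
        bins[idx].edges.append((u, v))
    return bins, ungeocodable
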