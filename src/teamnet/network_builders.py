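"""Teaming-network construction from per-patient visit sequences.

Three edge-construction rules are implemented, each applied patient by
patient to the time-sorted claim sequence and accumulated over patients:

binning
    Undirected.  An edge joins every pair of distinct vertices having two
    claims within ``|Δt| <= tau`` days (Δt = 0 qualifies).  Per patient a
    pair contributes weight 1 no matter how often it recurs; weights sum
    over patients.  Equivalent, at τ >= span, to the zero-diagonal
    unipartite projection of the binary patient×vertex incidence matrix.

sliding frame
    Directed.  Edge u→v for every ordered claim pair with ``0 < Δt <= tau``
    and u ≠ v.  Same-day pairs are excluded by the strict inequality.

trace-route
    Directed.  Edge u→v only for *consecutive* claims in the sorted
    sequence with ``0 < Δt <= tau``.  Self-loops u→u are permitted and
    tallied — they record a patient returning to the same provider, and
    are the reason trace-route networks can contain vertices the other
    constructions miss.

Every edge carries both weighting modes simultaneously:
``shared_patients`` (a patient counts once per edge) and ``total_visits``
(every qualifying claim pair counts).  Censoring always keys on the
shared-patients weight regardless of the configured mode.

Frame semantics are pairwise: an edge exists iff the pair's Δt satisfies
the rule above.  A consecutive trace-route pair with Δt > τ produces no
edge but does not break the chain for later pairs.  Builders stream one
patient at a time and never hold more than one patient's claim list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ALGORITHMS",
    "BuildConfig",
    "EdgeWeights",
    "TeamingNetwork",
    "build_binning",
    "build_network",
    "build_sliding_frame",
    "build_trace_route",
    "load_edgelist",
    "write_edgelist",
    "write_graphml",
]

ALGORITHMS = ("binning", "sliding", "trace_route")
WEIGHT_MODES = ("shared_patients", "total_visits")


@dataclass(frozen=True)
class BuildConfig:
    """Configuration for one network construction.

    ``include_self_loops`` is not a free choice: it is forced True for
    trace_route and False otherwise, matching each rule's definition.
    """

    algorithm: str = "binning"
    tau_days: int = 365
    level: str = "provider"
    weight_mode: str = "shared_patients"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.tau_days <= 0:
            raise ValueError("tau_days must be positive")
        if self.level not in ("provider", "organization"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    @property
    def include_self_loops(self) -> bool:
        return self.algorithm == "trace_route"

    @property
    def directed(self) -> bool:
        return self.algorithm in ("sliding", "trace_route")


@dataclass
class EdgeWeights:
    """Both weighting modes for one edge."""

    patients: int = 0  # number of distinct patients contributing the edge
    visits: int = 0  # total qualifying claim pairs over all patients


@dataclass
class TeamingNetwork:
    """A weighted provider- or organization-level teaming graph.

    ``edges`` maps an ordered pair (directed) or a sorted unordered pair
    (undirected) to its :class:`EdgeWeights`.  ``vertices`` is the set of
    edge endpoints, including vertices incident only to self-loops.
    """

    directed: bool
    edges: dict[tuple[str, str], EdgeWeights] = field(default_factory=dict)
    config: BuildConfig | None = None

    @property
    def vertices(self) -> set[str]:
        verts: set[str] = set()
        for u, v in self.edges:
            verts.add(u)
            verts.add(v)
        return verts

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def loop_edges(self) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[0] == e[1]]

    @property
    def loop_edge_count(self) -> int:
        return len(self.loop_edges)

    @property
    def loop_vertex_count(self) -> int:
        return len({u for u, v in self.edges if u == v})

    def weight(self, u: str, v: str, mode: str | None = None) -> int:
        """Edge weight Ω under *mode* (default: the build config's mode)."""
        mode = mode or (self.config.weight_mode if self.config else "shared_patients")
        key = (u, v) if self.directed else (min(u, v), max(u, v))
        w = self.edges.get(key)
        if w is None:
            return 0
        return w.patients if mode == "shared_patients" else w.visits

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Edges collapsed to unordered, loop-free pairs (for containment checks)."""
        return {(min(u, v), max(u, v)) for u, v in self.edges if u != v}

    def to_networkx(self, weight_mode: str | None = None):
        """Export as a networkx (Di)Graph with ``weight``, ``shared_patients``
        and ``total_visits`` edge attributes."""
        mode = weight_mode or (self.config.weight_mode if self.config else "shared_patients")
        G = nx.DiGraph() if self.directed else nx.Graph()
        for (u, v), w in self.edges.items():
            sel = w.patients if mode == "shared_patients" else w.visits
            G.add_edge(u, v, weight=sel, shared_patients=w.patients, total_visits=w.visits)
        return G


def _accumulate(
    totals: dict[tuple[str, str], EdgeWeights],
    patient_edges: dict[tuple[str, str], int],
) -> None:
    for key, visits in patient_edges.items():
        w = totals.get(key)
        if w is None:
            w = totals[key] = EdgeWeights()
        w.patients += 1
        w.visits += visits


def build_binning(
    sequences: Mapping[str, Iterable[tuple[str, int]]], config: BuildConfig | None = None
) -> TeamingNetwork:
    """Undirected co-occurrence network: all claim pairs within |Δt| <= τ."""
    config = config or BuildConfig(algorithm="binning")
    if config.algorithm != "binning":
        raise ValueError("config.algorithm must be 'binning'")
    tau = config.tau_days
    totals: dict[tuple[str, str], EdgeWeights] = {}
    for pid in sequences:
        claims = list(sequences[pid])
        patient_edges: dict[tuple[str, str], int] = {}
        n = len(claims)
        for i in range(n):
            vi, ti = claims[i]
            for j in range(i + 1, n):
                vj, tj = claims[j]
                if tj - ti > tau:  # sorted ascending: later j only larger
                    break
                if vi != vj:
                    key = (vi, vj) if vi < vj else (vj, vi)
                    patient_edges[key] = patient_edges.get(key, 0) + 1
        _accumulate(totals, patient_edges)
    return TeamingNetwork(directed=False, edges=totals, config=config)


def build_sliding_frame(
    sequences: Mapping[str, Iterable[tuple[str, int]]], config: BuildConfig | None = None
) -> TeamingNetwork:
    """Directed network over all ordered claim pairs with 0 < Δt <= τ."""
    config = config or BuildConfig(algorithm="sliding")
    if config.algorithm != "sliding":
        raise ValueError("config.algorithm must be 'sliding'")
    tau = config.tau_days
    totals: dict[tuple[str, str], EdgeWeights] = {}
    for pid in sequences:
        claims = list(sequences[pid])
        patient_edges: dict[tuple[str, str], int] = {}
        n = len(claims)
        for i in range(n):
            vi, ti = claims[i]
            for j in range(i + 1, n):
                vj, tj = claims[j]
                dt = tj - ti
                if dt > tau:
                    break
                if dt > 0 and vi != vj:
                    key = (vi, vj)
                    patient_edges[key] = patient_edges.get(key, 0) + 1
        _accumulate(totals, patient_edges)
    return TeamingNetwork(directed=True, edges=totals, config=config)


def build_trace_route(
    sequences: Mapping[str, Iterable[tuple[str, int]]], config: BuildConfig | None = None
) -> TeamingNetwork:
    """Directed network over consecutive claim pairs with 0 < Δt <= τ;
    self-loops permitted."""
    config = config or BuildConfig(algorithm="trace_route")
    if config.algorithm != "trace_route":
        raise ValueError("config.algorithm must be 'trace_route'")
    tau = config.tau_days
    totals: dict[tuple[str, str], EdgeWeights] = {}
    for pid in sequences:
        claims = list(sequences[pid])
        patient_edges: dict[tuple[str, str], int] = {}
        for (vi, ti), (vj, tj) in zip(claims, claims[1:]):
            dt = tj - ti
            if 0 < dt <= tau:
                key = (vi, vj)
                patient_edges[key] = patient_edges.get(key, 0) + 1
        _accumulate(totals, patient_edges)
    return TeamingNetwork(directed=True, edges=totals, config=config)


_BUILDERS = {
    "binning": build_binning,
    "sliding": build_sliding_frame,
    "trace_route": build_trace_route,
}


def build_network(
    sequences: Mapping[str, Iterable[tuple[str, int]]], config: BuildConfig
) -> TeamingNetwork:
    """Dispatch to the builder named by ``config.algorithm``."""
    return _BUILDERS[config.algorithm](sequences, config)


def write_edgelist(network: TeamingNetwork, path) -> None:
    """Write a weighted edge-list CSV.

    The first line is a ``#``-comment carrying the directedness flag and the
    build configuration; self-loop edges are written explicitly.  Edges are
    sorted so identical networks serialize byte-identically.
    """
    cfg = network.config
    meta = f"# directed={str(network.directed).lower()}"
    if cfg is not None:
        meta += (
            f" algorithm={cfg.algorithm} tau_days={cfg.tau_days}"
            f" level={cfg.level} weight_mode={cfg.weight_mode}"
        )
    with open(path, "w", newline="") as fh:
        fh.write(meta + "\n")
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "shared_patients", "total_visits"])
        for (u, v) in sorted(network.edges):
            w = network.edges[(u, v)]
            writer.writerow([u, v, w.patients, w.visits])


def load_edgelist(path) -> TeamingNetwork:
    """Read a network written by :func:`write_edgelist`."""
    with open(path, newline="") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("edge list missing metadata comment line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        directed = meta.get("directed", "true") == "true"
        config = None
        if "algorithm" in meta:
            config = BuildConfig(
                algorithm=meta["algorithm"],
                tau_days=int(meta["tau_days"]),
                level=meta["level"],
                weight_mode=meta["weight_mode"],
            )
        reader = csv.reader(fh)
        next(reader)  # column header
        edges: dict[tuple[str, str], EdgeWeights] = {}
        for u, v, wp, wv in reader:
            edges[(u, v)] = EdgeWeights(patients=int(wp), visits=int(wv))
    return TeamingNetwork(directed=directed, edges=edges, config=config)


def write_graphml(network: TeamingNetwork, path) -> None:
    """Write the network as GraphML via networkx (loops included)."""
    nx.write_graphml(network.to_networkx(), path)
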