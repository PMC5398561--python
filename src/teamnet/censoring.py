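"""Edge-weight censoring: the de-identification step applied to teaming networks.

Publicly released patient-sharing networks suppress low-weight edges so
that no patient can be re-identified from a unique combination of
providers ("unicity").  The CMS practice removes edges supported by
fewer than about eleven distinct beneficiaries; this module removes
every edge whose *shared-patients* weight is ``<= max_removed_weight``
(default 11, i.e. keep >= 12) and then drops vertices left isolated.

The censor always keys on the shared-patients weight, even when the
network was built with total-visit weights — de-identification is about
distinct beneficiaries, and both weights travel on every edge precisely
to make this possible.  The prose rule "fewer than eleven distinct
beneficiaries" corresponds to ``max_removed_weight=10``; both variants
are a parameter away.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .network_builders import TeamingNetwork

__all__ = ["CensorReport", "censor_network", "censor_sweep", "DEFAULT_MAX_REMOVED_WEIGHT"]

DEFAULT_MAX_REMOVED_WEIGHT = 11


@dataclass
class CensorReport:
    """Before/after bookkeeping for one censoring pass."""

    threshold: int
    edges_before: int
    edges_after: int
    vertices_before: int
    vertices_after: int
    lco_after: int
    isolated_vertices_removed: int
    fraction_edges_retained: float
    fraction_vertices_retained: float

    def to_dict(self) -> dict:
        return asdict(self)


def _lco(network: TeamingNetwork) -> int:
    if network.n_vertices == 0:
        return 0
    G = network.to_networkx()
    comps = (
        nx.weakly_connected_components(G) if network.directed else nx.connected_components(G)
    )
    return max(len(c) for c in comps)


def censor_network(
    network: TeamingNetwork, max_removed_weight: int = DEFAULT_MAX_REMOVED_WEIGHT
) -> tuple[TeamingNetwork, CensorReport]:
    """Remove edges with shared-patients weight <= *max_removed_weight*.

    Vertices with no surviving incident edge are removed with the edges;
    a threshold of 0 is the identity (all weights are >= 1).
    """
    if max_removed_weight < 0:
        raise ValueError("max_removed_weight must be >= 0")
    kept = {
        key: w for key, w in network.edges.items() if w.patients > max_removed_weight
    }
    censored = TeamingNetwork(directed=network.directed, edges=kept, config=network.config)
    v_before, v_after = network.n_vertices, censored.n_vertices
    report = CensorReport(
        threshold=max_removed_weight,
        edges_before=network.n_edges,
        edges_after=censored.n_edges,
        vertices_before=v_before,
        vertices_after=v_after,
        lco_after=_lco(censored),
        isolated_vertices_removed=v_before - v_after,
        fraction_edges_retained=(censored.n_edges / network.n_edges) if network.n_edges else 1.0,
        fraction_vertices_retained=(v_after / v_before) if v_before else 1.0,
    )
    return censored, report


def censor_sweep(
    network: TeamingNetwork, thresholds: Iterable[int] = range(1, 12)
) -> pd.DataFrame:
    """Censor at each threshold and tabulate retention (fragmentation sweep).

    Fractions retained are non-increasing in the threshold, giving the
    characteristic shape of an edge/vertex retention-vs-threshold table.
    """
    rows = [censor_network(network, t)[1].to_dict() for t in thresholds]
    return pd.DataFrame(rows)
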