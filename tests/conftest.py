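"""Shared fixtures and random-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teamnet.claims_io import ClaimsDataset
from teamnet.network_builders import EdgeWeights, TeamingNetwork


def random_sequences(
    rng: np.random.Generator,
    n_patients: int = 8,
    n_vertices: int = 6,
    max_claims: int = 8,
    span: int = 60,
    distinct_days: bool = True,
) -> dict[str, list[tuple[str, int]]]:
    """Random per-patient visit sequences, sorted ascending by day.

    ``distinct_days`` draws each patient's claim days without replacement,
    the regime in which the vertex-nesting containments between the three
    constructions hold exactly (same-day claim pairs are invisible to the
    strict 0 < Δt rules but not to binning).
    """
    vertices = [f"V{i:03d}" for i in range(n_vertices)]
    sequences = {}
    for p in range(n_patients):
        k = int(rng.integers(1, max_claims + 1))
        if distinct_days:
            k = min(k, span)
            days = sorted(rng.choice(span, size=k, replace=False).tolist())
        else:
            days = sorted(rng.integers(0, span, size=k).tolist())
        seq = [(vertices[int(rng.integers(n_vertices))], int(d)) for d in days]
        sequences[f"P{p:04d}"] = seq
    return sequences


def sequences_to_dataset(sequences: dict[str, list[tuple[str, int]]]) -> ClaimsDataset:
    """Lift raw sequences into a ClaimsDataset (organization = provider)."""
    rows = []
    base = pd.Timestamp("2013-01-01")
    for pid, seq in sequences.items():
        for vid, day in seq:
            rows.append((pid, vid.ljust(10, "0"), vid.ljust(10, "0"), base + pd.Timedelta(days=day)))
    frame = pd.DataFrame(
        rows, columns=["patient_id", "provider_id", "organization_id", "service_date"]
    )
    return ClaimsDataset(frame)


def make_undirected_network(
    edges: dict[tuple[str, str], int] | list[tuple[str, str]],
) -> TeamingNetwork:
    """Hand-build an undirected TeamingNetwork from pair -> weight (or pairs)."""
    if isinstance(edges, list):
        edges = {e: 1 for e in edges}
    ew = {
        (min(u, v), max(u, v)): EdgeWeights(patients=w, visits=w)
        for (u, v), w in edges.items()
    }
    return TeamingNetwork(directed=False, edges=ew)


def make_directed_network(
    edges: dict[tuple[str, str], int] | list[tuple[str, str]],
) -> TeamingNetwork:
    if isinstance(edges, list):
        edges = {e: 1 for e in edges}
    ew = {(u, v): EdgeWeights(patients=w, visits=w) for (u, v), w in edges.items()}
    return TeamingNetwork(directed=True, edges=ew)


@pytest.fixture
def rng():
    return np.random.default_rng(20130101)
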