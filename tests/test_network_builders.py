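"""Edge-construction algorithms: worked examples, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teamnet.network_builders import (
    BuildConfig,
    build_binning,
    build_network,
    build_sliding_frame,
    build_trace_route,
    load_edgelist,
    write_edgelist,
)

from conftest import random_sequences


def _cfg(algorithm, tau, mode="shared_patients"):
    return BuildConfig(algorithm=algorithm, tau_days=tau, weight_mode=mode)


def _weights(net, mode="shared_patients"):
    return {e: net.weight(*e, mode=mode) for e in net.edges}


# --------------------------------------------------------------------------
# worked examples (weights enumerated by hand from the pairwise conditions)
# --------------------------------------------------------------------------

class TestBinningExamples:
    def test_three_visits_make_complete_graph(self):
        net = build_binning({"p": [("A", 0), ("B", 10), ("C", 20)]}, _cfg("binning", 30))
        assert _weights(net) == {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1}
        assert not net.directed

    def test_recurring_pair_counts_once_per_patient(self):
        net = build_binning(
            {"p": [("A", 0), ("B", 10), ("A", 20), ("B", 25)]}, _cfg("binning", 30)
        )
        assert _weights(net) == {("A", "B"): 1}

    def test_pair_outside_frame_excluded(self):
        net = build_binning({"p": [("A", 0), ("B", 40)]}, _cfg("binning", 30))
        assert net.n_edges == 0

    def test_same_day_pair_included(self):
        net = build_binning({"p": [("A", 0), ("B", 0)]}, _cfg("binning", 30))
        assert _weights(net) == {("A", "B"): 1}

    def test_weights_sum_over_patients(self):
        seqs = {"p1": [("A", 0), ("B", 5)], "p2": [("A", 3), ("B", 9)], "p3": [("A", 0), ("C", 1)]}
        net = build_binning(seqs, _cfg("binning", 30))
        assert _weights(net) == {("A", "B"): 2, ("A", "C"): 1}

    def test_empty_input_gives_empty_network(self):
        assert build_binning({}, _cfg("binning", 30)).n_edges == 0


class TestSlidingExamples:
    def test_all_ordered_pairs_within_frame(self):
        net = build_sliding_frame({"p": [("A", 0), ("B", 10), ("C", 20)]}, _cfg("sliding", 30))
        assert _weights(net) == {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1}
        assert net.directed

    def test_same_day_pair_excluded_by_strict_inequality(self):
        net = build_sliding_frame({"p": [("A", 0), ("B", 0)]}, _cfg("sliding", 30))
        assert net.n_edges == 0

    def test_visit_weighting_counts_every_qualifying_pair(self):
        seqs = {"p": [("A", 0), ("B", 5), ("A", 10), ("B", 15)]}
        net = build_sliding_frame(seqs, _cfg("sliding", 30, "total_visits"))
        # qualifying ordered pairs: A0->B5, A0->B15, A10->B15 and B5->A10
        assert _weights(net, "total_visits") == {("A", "B"): 3, ("B", "A"): 1}
        assert _weights(net, "shared_patients") == {("A", "B"): 1, ("B", "A"): 1}

    def test_no_self_loops(self):
        net = build_sliding_frame({"p": [("A", 0), ("A", 5)]}, _cfg("sliding", 30))
        assert net.n_edges == 0


class TestTraceRouteExamples:
    def test_self_loop_recorded(self):
        net = build_trace_route({"p": [("A", 0), ("A", 5), ("B", 10)]}, _cfg("trace_route", 30))
        assert _weights(net) == {("A", "A"): 1, ("A", "B"): 1}
        assert net.loop_edge_count == 1
        assert net.loop_vertex_count == 1

    def test_only_consecutive_pairs(self):
        net = build_trace_route({"p": [("A", 0), ("B", 10), ("C", 20)]}, _cfg("trace_route", 30))
        assert _weights(net) == {("A", "B"): 1, ("B", "C"): 1}

    def test_long_gap_skips_pair_but_not_chain(self):
        net = build_trace_route({"p": [("A", 0), ("B", 40), ("C", 50)]}, _cfg("trace_route", 30))
        assert _weights(net) == {("B", "C"): 1}


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def _bipartite_projection(sequences):
    """Zero-diagonal binary bipartite projection: shared-patient counts."""
    vertices = sorted({v for seq in sequences.values() for v, _ in seq})
    vidx = {v: i for i, v in enumerate(vertices)}
    B = np.zeros((len(sequences), len(vertices)), dtype=int)
    for r, seq in enumerate(sequences.values()):
        for v, _ in seq:
            B[r, vidx[v]] = 1
    W = B.T @ B
    np.fill_diagonal(W, 0)
    return vertices, W


def _brute_sliding(sequences, tau):
    out = {}
    for pid, seq in sequences.items():
        seen = {}
        # all ordered claim-instance pairs; the strict 0 < dt condition means
        # each qualifying instance pair is counted exactly once
        for vi, ti in seq:
            for vj, tj in seq:
                if vi != vj and 0 < tj - ti <= tau:
                    seen[(vi, vj)] = seen.get((vi, vj), 0) + 1
        for key, cnt in seen.items():
            p, v = out.get(key, (0, 0))
            out[key] = (p + 1, v + cnt)
    return out


def _brute_trace(sequences, tau):
    out = {}
    for pid, seq in sequences.items():
        per = {}
        for (vi, ti), (vj, tj) in zip(seq, seq[1:]):
            if 0 < tj - ti <= tau:
                per[(vi, vj)] = per.get((vi, vj), 0) + 1
        for key, cnt in per.items():
            p, v = out.get(key, (0, 0))
            out[key] = (p + 1, v + cnt)
    return out


class TestOracles:
    def test_binning_equals_bipartite_projection_at_full_span(self, rng):
        for _ in range(25):
            seqs = random_sequences(rng, distinct_days=False)
            net = build_binning(seqs, _cfg("binning", 10_000))
            vertices, W = _bipartite_projection(seqs)
            for i, u in enumerate(vertices):
                for j, v in enumerate(vertices):
                    if i < j:
                        assert net.weight(u, v) == W[i, j]

    def test_sliding_matches_brute_force(self, rng):
        for _ in range(25):
            seqs = random_sequences(rng, distinct_days=False)
            tau = int(rng.integers(1, 40))
            net = build_sliding_frame(seqs, _cfg("sliding", tau))
            expected = _brute_sliding(seqs, tau)
            assert {e: (w.patients, w.visits) for e, w in net.edges.items()} == expected

    def test_trace_matches_brute_force(self, rng):
        for _ in range(25):
            seqs = random_sequences(rng, distinct_days=False)
            tau = int(rng.integers(1, 40))
            net = build_trace_route(seqs, _cfg("trace_route", tau))
            expected = _brute_trace(seqs, tau)
            assert {e: (w.patients, w.visits) for e, w in net.edges.items()} == expected


# --------------------------------------------------------------------------
# invariants
# --------------------------------------------------------------------------

class TestContainment:
    def test_nesting_with_distinct_days(self, rng):
        for _ in range(40):
            seqs = random_sequences(rng, distinct_days=True)
            tau = int(rng.integers(1, 40))
            b = build_binning(seqs, _cfg("binning", tau))
            s = build_sliding_frame(seqs, _cfg("sliding", tau))
            t = build_trace_route(seqs, _cfg("trace_route", tau))
            assert t.edge_pairs() <= s.edge_pairs() <= b.edge_pairs()
            assert s.vertices <= b.vertices <= t.vertices

    def test_binning_only_pairs_have_delta_t_zero_somewhere(self, rng):
        # with repeated days allowed, the binning/sliding pair difference
        # consists exactly of pairs whose only qualifying co-occurrences are
        # same-day claims
        for _ in range(20):
            seqs = random_sequences(rng, distinct_days=False, span=10)
            tau = int(rng.integers(1, 15))
            b = build_binning(seqs, _cfg("binning", tau))
            s = build_sliding_frame(seqs, _cfg("sliding", tau))
            assert s.edge_pairs() <= b.edge_pairs()
            for (u, v) in b.edge_pairs() - s.edge_pairs():
                found = [
                    (ti, tj)
                    for seq in seqs.values()
                    for vi, ti in seq
                    for vj, tj in seq
                    if {vi, vj} == {u, v} and abs(tj - ti) <= tau
                ]
                assert found and all(ti == tj for ti, tj in found)

    def test_same_day_claims_break_vertex_nesting(self):
        # documented edge case: a same-day pair is a binning edge but is
        # invisible to the strict 0 < dt rules, so binning can hold vertices
        # the trace-route network lacks
        seqs = {"p": [("A", 3), ("B", 3)]}
        b = build_binning(seqs, _cfg("binning", 10))
        t = build_trace_route(seqs, _cfg("trace_route", 10))
        assert b.vertices == {"A", "B"} and t.vertices == set()


@st.composite
def _sequences_strategy(draw):
    n_pat = draw(st.integers(1, 5))
    seqs = {}
    for p in range(n_pat):
        n = draw(st.integers(1, 6))
        days = sorted(draw(st.lists(st.integers(0, 50), min_size=n, max_size=n)))
        verts = draw(st.lists(st.sampled_from("ABCDE"), min_size=n, max_size=n))
        seqs[f"P{p}"] = list(zip(verts, days))
    return seqs


class TestProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seqs=_sequences_strategy(), tau=st.integers(1, 60))
    def test_shared_patient_weight_never_exceeds_visit_weight(self, seqs, tau):
        for algo in ("binning", "sliding", "trace_route"):
            net = build_network(seqs, _cfg(algo, tau))
            for e, w in net.edges.items():
                assert 1 <= w.patients <= w.visits

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seqs=_sequences_strategy(), tau=st.integers(1, 30))
    def test_edges_and_weights_monotone_in_tau(self, seqs, tau):
        for algo in ("binning", "sliding", "trace_route"):
            small = build_network(seqs, _cfg(algo, tau))
            large = build_network(seqs, _cfg(algo, tau + 10))
            assert set(small.edges) <= set(large.edges)
            for e, w in small.edges.items():
                assert w.patients <= large.edges[e].patients
                assert w.visits <= large.edges[e].visits


class TestSerialization:
    def test_edgelist_round_trip(self, tmp_path, rng):
        seqs = random_sequences(rng)
        net = build_trace_route(seqs, _cfg("trace_route", 20))
        path = tmp_path / "net.csv"
        write_edgelist(net, path)
        back = load_edgelist(path)
        assert back.directed == net.directed
        assert {e: (w.patients, w.visits) for e, w in back.edges.items()} == {
            e: (w.patients, w.visits) for e, w in net.edges.items()
        }
        assert back.config == net.config

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BuildConfig(algorithm="binning", tau_days=0)
        with pytest.raises(ValueError):
            BuildConfig(algorithm="bogus", tau_days=30)
        assert BuildConfig(algorithm="trace_route", tau_days=1).include_self_loops
        assert not BuildConfig(algorithm="binning", tau_days=1).include_self_loops
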