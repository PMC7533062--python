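"""The nine node measures against spec'd hand values and brute-force oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from ampconn.netmetrics import (
    eigenvector_centrality,
    gateway_coefficient,
    k_coreness,
    laplacian_centrality,
    metrics_table,
    participation_coefficient,
    weighted_betweenness,
    weighted_degree,
    weighted_transitivity,
    within_module_degree_z,
)
from conftest import random_partition, random_weighted_graph
from oracles import (
    barrat_oracle,
    betweenness_oracle,
    eigenvector_oracle,
    gateway_oracle,
    kcore_oracle,
    laplacian_centrality_oracle,
    participation_oracle,
    strength_oracle,
    wmdz_oracle,
)


def star(weights):
    g = nx.Graph()
    for i, w in enumerate(weights, start=1):
        g.add_edge(0, i, weight=w)
    return g


class TestDegree:
    def test_star_center(self):
        assert weighted_degree(star([2, 3, 4]), 0) == 9

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert weighted_degree(g, "x") == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            weighted_degree(star([1]), 99)


class TestBetweenness:
    def test_path_midpoint(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 2.0), ("b", "c", 2.0)])
        bet = weighted_betweenness(g)
        assert bet == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_triangle_all_zero(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        assert all(v == 0.0 for v in weighted_betweenness(g).values())

    @pytest.mark.parametrize("mode", ["reciprocal", "raw"])
    def test_matches_path_enumeration(self, rng, mode):
        g = random_weighted_graph(rng, 8, p_edge=0.5)
        got = weighted_betweenness(g, mode=mode)
        want = betweenness_oracle(g, mode=mode)
        for v in g.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-8)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            weighted_betweenness(nx.Graph(), mode="plain")


class TestTransitivity:
    def test_equal_weight_triangle_is_one(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 2.0), (1, 2, 2.0), (0, 2, 2.0)])
        for v in g.nodes:
            assert weighted_transitivity(g, v) == pytest.approx(1.0)

    def test_open_wedge_is_zero(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (0, 2, 3.0)])
        assert weighted_transitivity(g, 0) == 0.0

    def test_matches_barrat_formula(self, rng):
        g = random_weighted_graph(rng, 10, p_edge=0.5)
        for v in g.nodes:
            assert weighted_transitivity(g, v) == pytest.approx(barrat_oracle(g, v))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, 9, p_edge=0.6)
            for v in g.nodes:
                assert 0.0 <= weighted_transitivity(g, v) <= 1.0 + 1e-12


class TestCoreness:
    def test_k4_and_path(self):
        assert set(k_coreness(nx.complete_graph(4)).values()) == {3}
        assert set(k_coreness(nx.path_graph(5)).values()) == {1}

    def test_k4_with_pendant_matches_peeling(self):
        g = nx.Graph(list(nx.complete_graph(4).edges()) + [(3, 9)])
        assert k_coreness(g) == kcore_oracle(g)


class TestLaplacian:
    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node(0)
        assert laplacian_centrality(g, 0) == 0.0

    def test_p3_and_k3_eigentrace_values(self):
        p3 = nx.path_graph(3)
        assert laplacian_centrality(p3, 1) == 10.0
        assert laplacian_centrality(p3, 0) == 6.0
        k3 = nx.complete_graph(3)
        assert all(laplacian_centrality(k3, v) == 14.0 for v in k3.nodes)

    def test_matches_eigenvalue_trace_oracle(self, rng):
        g = random_weighted_graph(rng, 9, p_edge=0.4)
        for v in g.nodes:
            assert laplacian_centrality(g, v) == pytest.approx(
                laplacian_centrality_oracle(g, v)
            )


class TestEigenvector:
    def test_regular_graph_all_one(self):
        g = nx.cycle_graph(6)
        nx.set_edge_attributes(g, 1.5, "weight")
        assert all(
            s == pytest.approx(1.0) for s in eigenvector_centrality(g).values()
        )

    def test_star_center_dominates(self):
        g = star([1, 1, 1, 1])
        scores = eigenvector_centrality(g)
        assert scores[0] == pytest.approx(1.0)
        leaves = [scores[v] for v in g.nodes if v != 0]
        assert len(set(np.round(leaves, 12))) == 1
        assert leaves[0] < 1.0

    def test_empty_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            eigenvector_centrality(g)

    def test_matches_power_iteration(self, rng):
        g = random_weighted_graph(rng, 10, p_edge=0.5, allow_isolates=False)
        got = eigenvector_centrality(g)
        want = eigenvector_oracle(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-8)


class TestModuleMeasures:
    def test_intra_only_participation_zero(self):
        g = star([1, 1])
        part = {v: 1 for v in g.nodes}
        assert participation_coefficient(g, part)[0] == 0.0

    def test_equal_split_two_and_four_modules(self):
        g = star([1, 1])
        assert participation_coefficient(g, {0: 1, 1: 1, 2: 2})[0] == pytest.approx(0.5)
        g4 = star([1, 1, 1, 1])
        part = {0: 1, 1: 1, 2: 2, 3: 3, 4: 4}
        assert participation_coefficient(g4, part)[0] == pytest.approx(0.75)

    def test_gateway_reduces_to_participation_intra_only(self):
        g = star([1, 1])
        part = {v: 1 for v in g.nodes}
        assert gateway_coefficient(g, part)[0] == 0.0

    def test_gateway_dominates_participation(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, 10, p_edge=0.5)
            part = random_partition(rng, g.nodes, 3)
            p = participation_coefficient(g, part)
            gw = gateway_coefficient(g, part)
            for v in g.nodes:
                assert gw[v] >= p[v] - 1e-12

    def test_unknown_gateway_variant_rejected(self):
        with pytest.raises(ValueError):
            gateway_coefficient(nx.Graph(), {}, "strength")

    def test_wmdz_ignores_inter_module_edges(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (2, 3, 4.0), (0, 9, 7.0)])
        part = {0: 1, 1: 1, 2: 1, 3: 1, 9: 2}
        with_inter = within_module_degree_z(g, part)
        g.remove_edge(0, 9)
        without = within_module_degree_z(g, part)
        for v in (0, 1, 2, 3):
            assert with_inter[v] == pytest.approx(without[v])

    def test_constant_intra_strength_gives_zero(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 2.0), (2, 3, 2.0)])
        part = {v: 1 for v in g.nodes}
        assert all(z == 0.0 for z in within_module_degree_z(g, part).values())

    @pytest.mark.parametrize("measure_oracle", [
        (participation_coefficient, participation_oracle),
        (gateway_coefficient, gateway_oracle),
        (within_module_degree_z, wmdz_oracle),
    ], ids=["PART", "GATE", "WMDZ"])
    def test_matches_formula_oracle(self, rng, measure_oracle):
        impl, oracle = measure_oracle
        g = random_weighted_graph(rng, 11, p_edge=0.4)
        part = random_partition(rng, g.nodes, 4)
        got = impl(g, part)
        for v in g.nodes:
            assert got[v] == pytest.approx(oracle(g, v, part), abs=1e-10)


class TestScaleBehavior:
    def test_weight_rescaling(self, rng):
        g = random_weighted_graph(rng, 9, p_edge=0.5, allow_isolates=False)
        part = random_partition(rng, g.nodes, 3)
        c = 3.7
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for u, v, w in g.edges(data="weight"):
            h.add_edge(u, v, weight=c * w)
        for v in g.nodes:
            assert weighted_degree(h, v) == pytest.approx(c * weighted_degree(g, v))
            assert weighted_transitivity(h, v) == pytest.approx(
                weighted_transitivity(g, v)
            )
        assert k_coreness(h) == k_coreness(g)
        for v in g.nodes:
            assert laplacian_centrality(h, v) == laplacian_centrality(g, v)
        eg, eh = eigenvector_centrality(g), eigenvector_centrality(h)
        pg, ph = participation_coefficient(g, part), participation_coefficient(h, part)
        for v in g.nodes:
            assert eh[v] == pytest.approx(eg[v], abs=1e-9)
            assert ph[v] == pytest.approx(pg[v], abs=1e-12)


class TestMetricsTable:
    def test_empty_graph_consistent_zeros(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        tbl = metrics_table(g, {v: 1.0 for v in g.nodes}, {v: 1 for v in g.nodes})
        assert (tbl[["DEG", "BET", "TRA", "KVL", "LAP", "EIG"]] == 0).all().all()

    def test_column_order_stable(self, rng):
        g = random_weighted_graph(rng, 6, p_edge=0.6)
        part = random_partition(rng, g.nodes, 2)
        amps = {v: float(v) for v in g.nodes}
        t1 = metrics_table(g, amps, part)
        t2 = metrics_table(g, amps, part)
        assert list(t1.columns) == [
            "amplitude", "DEG", "BET", "TRA", "KVL", "LAP", "EIG",
            "PART", "GATE", "WMDZ",
        ]
        assert t1.equals(t2)

    def test_missing_amplitude_rejected(self, rng):
        g = random_weighted_graph(rng, 4, p_edge=0.9)
        with pytest.raises(ValueError, match="amplitude"):
            metrics_table(g, {0: 1.0}, {v: 1 for v in g.nodes})

    def test_ten_node_fixture_matches_all_oracles(self, rng):
        g = random_weighted_graph(rng, 10, p_edge=0.5, allow_isolates=False)
        part = random_partition(rng, g.nodes, 3)
        amps = {v: float(rng.uniform(1, 10)) for v in g.nodes}
        tbl = metrics_table(g, amps, part)
        bet = betweenness_oracle(g)
        eig = eigenvector_oracle(g)
        core = kcore_oracle(g)
        for v in g.nodes:
            row = tbl.loc[v]
            assert row["DEG"] == pytest.approx(strength_oracle(g, v))
            assert row["BET"] == pytest.approx(bet[v], abs=1e-8)
            assert row["TRA"] == pytest.approx(barrat_oracle(g, v))
            assert row["KVL"] == core[v]
            assert row["LAP"] == pytest.approx(laplacian_centrality_oracle(g, v))
            assert row["EIG"] == pytest.approx(eig[v], abs=1e-8)
            assert row["PART"] == pytest.approx(participation_oracle(g, v, part))
            assert row["GATE"] == pytest.approx(gateway_oracle(g, v, part))
            assert row["WMDZ"] == pytest.approx(wmdz_oracle(g, v, part))
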