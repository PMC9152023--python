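import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fosnet import (ValidationError, assortativity,
                    betweenness, centrality_table, char_path_length,
                    correlation_matrix, degree, markov_cluster, modularity,
                    select_inflation, small_worldness, summarize,
                    threshold_network, transitivity)
from fosnet.mcl import ClusterAssignment
from fosnet.network_metrics import FunctionalNetwork
from conftest import make_table
from oracles import (brute_assortativity, brute_betweenness,
                     brute_char_path_length, brute_modularity,
                     brute_transitivity, reference_mcl_partition)


def from_nx(g: nx.Graph) -> FunctionalNetwork:
    return FunctionalNetwork.from_graph(nx.relabel_nodes(g, str))


class TestThresholding:
    def test_rule_matches_nested_loops(self):
        rng = np.random.default_rng(8)
        table = make_table({("male", "naive"): rng.uniform(1, 9, size=(5, 5))})
        corr = correlation_matrix(table, ("male", "naive"))
        net = threshold_network(corr, 0.3)
        for i, a in enumerate(corr.region_order):
            for j, b in enumerate(corr.region_order):
                expect = (i != j and corr.r.iloc[i, j] > 0
                          and corr.p.iloc[i, j] < 0.3)
                assert bool(net.adjacency.iloc[i, j]) == expect

    def test_negative_correlations_never_edges(self):
        a = [1.0, 2.0, 3.0, 4.0]
        table = make_table({("male", "naive"): np.column_stack(
            [a, [10.5 - x + 0.001 * (x ** 2) for x in a]])})
        corr = correlation_matrix(table, ("male", "naive"))
        assert corr.r.iloc[0, 1] < -0.99
        assert corr.p.iloc[0, 1] < 0.05
        assert threshold_network(corr, 0.05).n_edges == 0

    def test_perfect_positive_matrix_is_complete(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        table = make_table({("male", "naive"): np.column_stack([a, 2 * a, a + 1])})
        net = threshold_network(correlation_matrix(table, ("male", "naive")), 0.05)
        assert net.n_edges == 3

    def test_threshold_bounds_checked(self):
        table = make_table({("male", "naive"): np.random.default_rng(0).uniform(1, 9, (4, 3))})
        corr = correlation_matrix(table, ("male", "naive"))
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                threshold_network(corr, bad)


class TestNodeMeasures:
    @pytest.mark.parametrize("graph,expected", [
        (nx.star_graph(4), {0: 4, 1: 1, 2: 1, 3: 1, 4: 1}),
        (nx.complete_graph(5), {i: 4 for i in range(5)}),
        (nx.path_graph(4), {0: 1, 1: 2, 2: 2, 3: 1}),
    ])
    def test_degree_examples(self, graph, expected):
        d = degree(from_nx(graph))
        assert {int(k): v for k, v in d.items()} == expected

    def test_betweenness_star_center_is_one(self):
        b = betweenness(from_nx(nx.star_graph(4)))
        assert b["0"] == pytest.approx(1.0)
        assert b.drop("0").max() == pytest.approx(0.0)

    def test_betweenness_cycle_symmetric(self):
        b = betweenness(from_nx(nx.cycle_graph(5)))
        assert b.nunique() == 1

    def test_betweenness_matches_path_enumeration_oracle(self):
        for seed in range(5):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            net = from_nx(g)
            adj = net.adjacency.to_numpy()
            active = adj.sum(axis=1) > 0
            oracle = brute_betweenness(adj)[active]
            mine = betweenness(net).to_numpy()
            assert np.allclose(mine, oracle, atol=1e-12)

    def test_centrality_table_degree_sum_and_ranks(self):
        net = from_nx(nx.gnp_random_graph(12, 0.3, seed=1))
        ct = centrality_table(net)
        assert ct.frame["degree"].sum() == 2 * net.n_edges
        assert ct.frame["rank_degree"].min() == 1


class TestGraphMeasures:
    def test_transitivity_examples(self):
        assert transitivity(from_nx(nx.complete_graph(4))) == pytest.approx(1.0)
        assert transitivity(from_nx(nx.star_graph(4))) == pytest.approx(0.0)
        square_diag = nx.cycle_graph(4)
        square_diag.add_edge(0, 2)
        # brute force: 2 triangles, 8 connected triples -> 6/8
        assert transitivity(from_nx(square_diag)) == pytest.approx(
            brute_transitivity(nx.to_numpy_array(square_diag)))
        assert transitivity(from_nx(square_diag)) == pytest.approx(0.75)

    def test_assortativity_examples_and_oracle(self):
        assert assortativity(from_nx(nx.star_graph(5))) == pytest.approx(-1.0)
        assert math.isnan(assortativity(from_nx(nx.cycle_graph(6))))
        g = nx.gnp_random_graph(10, 0.4, seed=3)
        assert assortativity(from_nx(g)) == pytest.approx(
            brute_assortativity(nx.to_numpy_array(g)), rel=1e-9)

    def test_char_path_length_conventions(self):
        assert char_path_length(from_nx(nx.complete_graph(5))) == pytest.approx(1.0)
        assert char_path_length(from_nx(nx.path_graph(3))) == pytest.approx(4 / 3)
        two_triangles = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert char_path_length(from_nx(two_triangles)) == pytest.approx(1.0)

    def test_small_worldness_er_input_near_one(self):
        net = from_nx(nx.gnm_random_graph(40, 160, seed=2))
        s = small_worldness(net, n_random=100, seed=0)
        assert 0.75 < s < 1.3

    def test_small_worldness_clustered_ring_exceeds_one(self):
        g = nx.ring_of_cliques(10, 6)
        s = small_worldness(from_nx(g), n_random=50, seed=0)
        assert s > 1.5

    def test_small_worldness_deterministic_given_seed(self):
        net = from_nx(nx.gnm_random_graph(20, 50, seed=5))
        assert small_worldness(net, n_random=20, seed=3) == \
            small_worldness(net, n_random=20, seed=3)


class TestMarkovClustering:
    def test_disjoint_triangles_are_two_clusters(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        ca = markov_cluster(from_nx(g), 2.0)
        assert ca.n_clusters == 2
        assert set(ca.members(0)) == {"0", "1", "2"}

    def test_complete_graph_is_one_cluster(self):
        assert markov_cluster(from_nx(nx.complete_graph(6)), 2.0).n_clusters == 1

    def test_barbell_splits_at_bridge_matching_reference(self):
        g = nx.barbell_graph(5, 0)
        ca = markov_cluster(from_nx(g), 2.0)
        mine = {frozenset(int(n) for n in ca.members(c))
                for c in range(ca.n_clusters)}
        ref = reference_mcl_partition(nx.to_numpy_array(g), 2.0)
        assert mine == ref == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_invariant_to_node_relabeling(self):
        g = nx.ring_of_cliques(4, 4)
        net = from_nx(g)
        ca = markov_cluster(net, 2.0)
        perm = np.random.default_rng(0).permutation(net.region_order)
        shuffled = FunctionalNetwork(adjacency=net.adjacency.loc[perm, perm])
        ca2 = markov_cluster(shuffled, 2.0)
        part1 = {frozenset(ca.members(c)) for c in range(ca.n_clusters)}
        part2 = {frozenset(ca2.members(c)) for c in range(ca2.n_clusters)}
        assert part1 == part2

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValidationError):
            markov_cluster(from_nx(nx.complete_graph(3)), 1.0)


class TestModularityAndInflationSelection:
    def test_single_community_q_zero(self):
        net = from_nx(nx.gnp_random_graph(8, 0.5, seed=0))
        labels = pd.Series(0, index=net.active_nodes)
        ca = ClusterAssignment(labels=labels, inflation=2.0, n_iterations=0)
        assert modularity(net, ca) == pytest.approx(0.0, abs=1e-12)

    def test_two_k4_correct_split_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        net = from_nx(g)
        labels = pd.Series([0] * 4 + [1] * 4, index=[str(i) for i in range(8)])
        ca = ClusterAssignment(labels=labels, inflation=2.0, n_iterations=0)
        # hand evaluation: e_cc = 1/2 each, a_c = 1/2 each -> Q = 2*(1/2 - 1/4)
        assert modularity(net, ca) == pytest.approx(0.5)
        adj = net.adjacency.to_numpy()
        assert brute_modularity(adj, labels.to_numpy()) == pytest.approx(0.5)

    def test_q_in_valid_range_for_random_partitions(self):
        net = from_nx(nx.gnp_random_graph(12, 0.3, seed=2))
        rng = np.random.default_rng(0)
        for _ in range(10):
            labels = pd.Series(rng.integers(0, 3, len(net.active_nodes)),
                               index=net.active_nodes)
            q = modularity(net, ClusterAssignment(labels, 2.0, 0))
            assert -0.5 - 1e-9 <= q <= 1.0

    def test_select_inflation_recovers_three_planted_blocks(self):
        g = nx.ring_of_cliques(3, 7)  # 3 cliques, single bridges
        ca = select_inflation(from_nx(g))
        assert ca.n_clusters == 3
        assert ca.modularity_q > 0.5

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            select_inflation(from_nx(nx.complete_graph(3)), grid=[])


class TestSummary:
    def test_summarize_fields_consistent(self):
        net = from_nx(nx.ring_of_cliques(4, 5))
        s = summarize(net, n_random=20, seed=0)
        assert s.n_active_nodes == 20
        assert s.n_edges == net.n_edges
        assert s.transitivity == pytest.approx(transitivity(net))
        assert s.char_path_length == pytest.approx(
            brute_char_path_length(net.adjacency.to_numpy()))
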