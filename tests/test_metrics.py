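"""Metric correctness against enumeration and networkx oracles."""

import numpy as np
import networkx as nx
import pytest

from conftest import make_network, random_network
from neurodecay import (average_path_length, clustering_coefficient,
                        efficiency_histogram, global_efficiency,
                        lscc_fraction, path_weights, total_strength)
from neurodecay.metrics import ParameterError
from neurodecay.network import AFFECTED, REMOVED


def to_networkx(net):
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n))
    mask = net.functional_mask
    for s, d, e in zip(net.src[mask], net.dst[mask], net.eps[mask]):
        g.add_edge(int(s), int(d), weight=1.0 / e)
    return g


class TestLSCC:
    def test_complete_digraph(self):
        edges = [(i, j) for i in range(6) for j in range(6) if i != j]
        assert lscc_fraction(make_network(6, edges)) == 1.0

    def test_disjoint_cycles(self):
        # cycles of size 5 and 3 on 8 nodes -> 5/8
        edges = [(i, (i + 1) % 5) for i in range(5)]
        edges += [(5 + i, 5 + (i + 1) % 3) for i in range(3)]
        assert lscc_fraction(make_network(8, edges)) == 0.625

    def test_dag_gives_singletons(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        assert lscc_fraction(make_network(5, edges)) == 1 / 5

    def test_no_functional_edges(self):
        net = make_network(4, [(0, 1)])
        net.state[:] = REMOVED
        net.eps[:] = net.eps0 * np.exp(-2.0)
        assert lscc_fraction(net) == 1 / 4


class TestPathWeights:
    def test_reciprocal_pair(self):
        net = make_network(2, [(0, 1), (1, 0)])
        w = path_weights(net)
        assert w[0, 1] == 1.0 and w[1, 0] == 1.0

    def test_three_cycle_enumeration(self, three_cycle):
        w = path_weights(three_cycle)
        assert w[0, 1] == 1.0 and w[0, 2] == 2.0

    def test_chain_additivity_of_resistances(self):
        # strengths 0.5 and 0.25 -> weights 2 and 4 -> w(A,C) = 6
        net = make_network(3, [(0, 1), (1, 2)], [0.5, 0.25])
        assert path_weights(net)[0, 2] == pytest.approx(6.0)


class TestGlobalEfficiency:
    def test_reciprocal_pair(self):
        assert global_efficiency(make_network(2, [(0, 1), (1, 0)])) == 1.0

    def test_three_cycle(self, three_cycle):
        # pairs: three at weight 1, three at weight 2
        assert global_efficiency(three_cycle) == pytest.approx(0.75)

    def test_no_edges_gives_zero(self):
        net = make_network(5, [(0, 1)])
        net.state[:] = REMOVED
        net.eps[:] = net.eps0 * np.exp(-2.0)
        assert global_efficiency(net) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ParameterError):
            global_efficiency(make_network(1, np.empty((0, 2))))

    def test_strength_scaling(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 20, 60, unit_weights=False)
        scaled = net.copy()
        scaled.eps0 = scaled.eps0 * 0.5
        scaled.eps = scaled.eps * 0.5
        assert global_efficiency(scaled) == pytest.approx(
            0.5 * global_efficiency(net), rel=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        net = random_network(rng, 15, 50, unit_weights=False)
        perm = rng.permutation(15)
        relabeled = make_network(
            15, np.c_[perm[net.src], perm[net.dst]], net.eps0)
        assert global_efficiency(relabeled) == pytest.approx(
            global_efficiency(net), rel=1e-12)


class TestOracleEquivalence:
    """LSCC / path weights / GE against networkx on random graphs."""

    @pytest.mark.parametrize("trial", range(10))
    def test_random_graphs_match_networkx(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 40))
        m = int(rng.integers(n, min(3 * n, n * (n - 1))))
        net = random_network(rng, n, m, unit_weights=bool(trial % 2))
        # partially decay some edges to exercise the functional filter
        k = m // 4
        net.state[:k] = AFFECTED
        net.affected_at[:k] = 0
        net.eps[:k] = net.eps0[:k] * np.exp(-0.5)
        net.state[k:k + m // 5] = REMOVED
        net.eps[k:k + m // 5] = net.eps0[k:k + m // 5] * np.exp(-1.5)

        g = to_networkx(net)
        f_oracle = max(len(c) for c in nx.strongly_connected_components(g)) / n
        assert lscc_fraction(net) == pytest.approx(f_oracle, abs=1e-10)

        dist_oracle = dict(nx.all_pairs_dijkstra_path_length(g))
        w = path_weights(net)
        inv_sum = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = dist_oracle.get(i, {}).get(j, np.inf)
                assert w[i, j] == pytest.approx(d, abs=1e-10)
                if np.isfinite(d) and d > 0:
                    inv_sum += 1.0 / d
        assert global_efficiency(net) == pytest.approx(
            inv_sum / (n * (n - 1)), abs=1e-10)

    @pytest.mark.parametrize("trial", range(3))
    def test_clustering_matches_networkx(self, trial):
        rng = np.random.default_rng(2000 + trial)
        net = random_network(rng, 50, 400)
        und = nx.Graph(to_networkx(net))
        assert clustering_coefficient(net) == pytest.approx(
            nx.average_clustering(und), abs=1e-12)


class TestClustering:
    def test_complete_triangle(self):
        edges = [(i, j) for i in range(3) for j in range(3) if i != j]
        assert clustering_coefficient(make_network(3, edges)) == 1.0

    def test_star_has_no_triangles(self):
        edges = [(0, i) for i in range(1, 6)]
        assert clustering_coefficient(make_network(6, edges)) == 0.0


class TestAveragePathLength:
    def test_three_cycle(self, three_cycle):
        assert average_path_length(three_cycle) == pytest.approx(1.5)

    def test_complete_digraph(self):
        edges = [(i, j) for i in range(5) for j in range(5) if i != j]
        assert average_path_length(make_network(5, edges)) == 1.0

    def test_unit_weights_equal_hop_distance(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 30, 120)
        g = to_networkx(net)
        hops = [d for _, lengths in nx.all_pairs_shortest_path_length(g)
                for t, d in lengths.items() if d > 0]
        assert average_path_length(net) == pytest.approx(np.mean(hops))

    def test_no_reachable_pair_is_undefined(self):
        net = make_network(3, [(0, 1)])
        net.state[:] = REMOVED
        net.eps[:] = net.eps0 * np.exp(-2.0)
        assert average_path_length(net) is None


class TestEfficiencyHistogram:
    def test_three_cycle_bins(self, three_cycle):
        h = efficiency_histogram(three_cycle, bin_edges=[0.0, 0.5, 1.0])
        assert h.counts.tolist() == [3, 3]  # 1/2-efficiency and 1.0 (closed)

    def test_counts_sum_to_reachable_pairs(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, 25, 80, unit_weights=False)
        h = efficiency_histogram(net)
        w = path_weights(net)
        np.fill_diagonal(w, np.inf)
        assert h.total() == int(np.isfinite(w).sum())

    def test_empty_network(self):
        net = make_network(4, [(0, 1)])
        net.state[:] = REMOVED
        net.eps[:] = net.eps0 * np.exp(-2.0)
        assert efficiency_histogram(net).total() == 0

    def test_non_monotone_edges_rejected(self, three_cycle):
        with pytest.raises(ParameterError):
            efficiency_histogram(three_cycle, bin_edges=[0.5, 0.2, 1.0])


class TestTotalStrength:
    def test_fresh_identical_network(self, small_world_net):
        assert total_strength(small_world_net) == small_world_net.m

    def test_removed_edges_do_not_count(self):
        net = make_network(3, [(0, 1), (1, 2), (2, 0)])
        net.state[0] = REMOVED
        net.eps[0] = net.eps0[0] * np.exp(-1.5)
        assert total_strength(net) == 2.0
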