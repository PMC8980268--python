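"""Graph metrics against closed forms and independent brute-force oracles."""

import numpy as np
import pytest

import networkx as nx

from hemnet import HemisphericNetwork
from hemnet.metrics import (
    assortativity_coefficient,
    betweenness_centrality,
    compute_metric_set,
    local_efficiency,
    modularity_q,
    modularity_repeated,
    nodal_and_global_efficiency,
    node_degree,
    shortest_paths,
)

from _oracles import (
    apsp_oracle,
    assortativity_oracle,
    betweenness_oracle,
    local_efficiency_oracle,
    max_modularity_oracle,
    modularity_q_oracle,
    random_weighted_graph,
)


def as_net(weights, sparsity=0.5):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    return HemisphericNetwork(
        roi_labels=[f"roi{i + 1:02d}" for i in range(n)],
        weights=weights,
        sparsity=sparsity,
        n_edges=int(np.count_nonzero(np.triu(weights, 1))),
    )


def complete_graph(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return m


def star_graph(n):
    m = np.zeros((n, n))
    m[0, 1:] = m[1:, 0] = 1.0
    return m


def path_graph(weights):
    n = len(weights) + 1
    m = np.zeros((n, n))
    for i, w in enumerate(weights):
        m[i, i + 1] = m[i + 1, i] = w
    return m


def two_triangles():
    m = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        m[a, b] = m[b, a] = 1.0
    return m


class TestShortestPaths:
    def test_unit_path_distances(self):
        d = shortest_paths(as_net(path_graph([1.0, 1.0]))).d
        assert d[0, 2] == 2.0

    def test_half_weights_double_lengths(self):
        d = shortest_paths(as_net(path_graph([0.5, 0.5]))).d
        assert d[0, 1] == 2.0
        assert d[0, 2] == 4.0

    def test_disconnected_pair_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_paths(as_net(w)).d
        assert np.isinf(d[0, 2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(20, 0.3, rng)
        d = shortest_paths(as_net(w)).d
        np.testing.assert_allclose(d, apsp_oracle(w), atol=1e-10)


class TestDegreeAndEfficiency:
    def test_complete_graph_closed_forms(self):
        net = as_net(complete_graph(45))
        np.testing.assert_allclose(node_degree(net), 44.0)
        e_nodal, e_global = nodal_and_global_efficiency(shortest_paths(net))
        np.testing.assert_allclose(e_nodal, 1.0)
        assert e_global == pytest.approx(1.0)

    def test_path_degree(self):
        net = as_net(path_graph([0.5, 0.7]))
        np.testing.assert_allclose(node_degree(net), [0.5, 1.2, 0.7])

    def test_isolated_node_zero_degree(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert node_degree(as_net(w))[2] == 0.0

    def test_unit_path_nodal_efficiency(self):
        e_nodal, _ = nodal_and_global_efficiency(shortest_paths(as_net(path_graph([1, 1]))))
        assert e_nodal[0] == pytest.approx((1 + 0.5) / 2)

    def test_disconnected_nodes_zero_efficiency(self):
        _, e_global = nodal_and_global_efficiency(shortest_paths(as_net(np.zeros((2, 2)))))
        assert e_global == 0.0


class TestLocalEfficiency:
    def test_triangle_all_ones(self):
        np.testing.assert_allclose(local_efficiency(as_net(complete_graph(3))), 1.0)

    def test_star_graph_zero(self):
        np.testing.assert_allclose(local_efficiency(as_net(star_graph(6))), 0.0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_subgraph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(12, 0.4, rng)
        np.testing.assert_allclose(
            local_efficiency(as_net(w)), local_efficiency_oracle(w), atol=1e-10
        )


class TestBetweenness:
    def test_star_center_dominates(self):
        bc = betweenness_centrality(as_net(star_graph(5)))
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_complete_graph_zero(self):
        np.testing.assert_allclose(betweenness_centrality(as_net(complete_graph(6))), 0.0)

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(8, 0.4, rng)
        np.testing.assert_allclose(
            betweenness_centrality(as_net(w)), betweenness_oracle(w), atol=1e-10
        )

    def test_matches_networkx_on_larger_graph(self):
        rng = np.random.default_rng(9)
        w = random_weighted_graph(15, 0.3, rng)
        g = nx.from_numpy_array(w)
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        ref = nx.betweenness_centrality(g, weight="length", normalized=True)
        np.testing.assert_allclose(
            betweenness_centrality(as_net(w)), [ref[i] for i in range(15)], atol=1e-8
        )


class TestModularity:
    def test_two_triangles_q_half(self):
        w = two_triangles()
        mean_q, best, best_q = modularity_repeated(w, n_runs=20,
                                                   rng=np.random.default_rng(0))
        assert best_q == pytest.approx(0.5, abs=1e-12)
        # partition groups the two triangles
        assert len(set(best[:3])) == 1 and len(set(best[3:])) == 1
        assert best[0] != best[3]
        assert max_modularity_oracle(w) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_q_matches_formula_oracle(self):
        rng = np.random.default_rng(1)
        w = random_weighted_graph(7, 0.5, rng)
        comm = np.zeros(7, dtype=int)
        q = modularity_q(w, comm)
        assert q == pytest.approx(modularity_q_oracle(w, comm), abs=1e-12)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_q_formula_matches_networkx(self):
        rng = np.random.default_rng(2)
        w = random_weighted_graph(10, 0.4, rng)
        comm = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        g = nx.from_numpy_array(w)
        communities = [{i for i in range(10) if comm[i] == c} for c in range(3)]
        ref = nx.community.modularity(g, communities, weight="weight")
        assert modularity_q(w, comm) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(6, 3), (7, 4), (8, 5)])
    def test_heuristic_near_exhaustive_optimum(self, n, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(n, 0.5, rng)
        if w.sum() == 0:
            pytest.skip("empty draw")
        q_max = max_modularity_oracle(w)
        mean_q, _, best_q = modularity_repeated(w, n_runs=50,
                                                rng=np.random.default_rng(seed))
        assert best_q <= q_max + 1e-10
        assert mean_q <= q_max + 1e-10
        assert best_q >= 0.95 * q_max - 1e-12

    def test_edgeless_network_rejected(self):
        with pytest.raises(ValueError, match="at least one edge"):
            modularity_repeated(np.zeros((4, 4)), n_runs=5)

    def test_mean_q_stable_across_seeds_on_45_node_fixture(self):
        """500-run averages agree to 3 decimals between independent seeds."""
        rng = np.random.default_rng(10)
        base = random_weighted_graph(45, 0.1, rng)
        labels = np.repeat(np.arange(5), 9)
        for i in range(45):
            for j in range(i + 1, 45):
                if labels[i] == labels[j] and rng.random() < 0.6:
                    base[i, j] = base[j, i] = rng.uniform(0.5, 1.0)
        q1, _, _ = modularity_repeated(base, n_runs=500, rng=np.random.default_rng(1))
        q2, _, _ = modularity_repeated(base, n_runs=500, rng=np.random.default_rng(2))
        assert abs(q1 - q2) < 1e-3


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self):
        w = star_graph(6)
        assert assortativity_coefficient(as_net(w)) == pytest.approx(-1.0, abs=1e-12)
        assert assortativity_oracle(w) == pytest.approx(-1.0, abs=1e-12)

    def test_complete_graph_undefined(self):
        assert np.isnan(assortativity_coefficient(as_net(complete_graph(5))))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_newman_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(12, 0.4, rng)
        ours = assortativity_coefficient(as_net(w))
        ref = assortativity_oracle(w)
        assert ours == pytest.approx(ref, abs=1e-10)


class TestMetricSet:
    def test_complete_graph_summary(self):
        ms = compute_metric_set(as_net(complete_graph(10)), n_modularity_runs=5,
                                rng=np.random.default_rng(0))
        np.testing.assert_allclose(ms.degree, 9.0)
        assert ms.e_global == pytest.approx(1.0)
        np.testing.assert_allclose(ms.betweenness, 0.0)
        assert np.isnan(ms.assortativity)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(14)
        w = random_weighted_graph(20, 0.3, rng)
        a = compute_metric_set(as_net(w), n_modularity_runs=30, rng=np.random.default_rng(3))
        b = compute_metric_set(as_net(w), n_modularity_runs=30, rng=np.random.default_rng(3))
        assert a.modularity_mean == b.modularity_mean
        np.testing.assert_array_equal(a.betweenness, b.betweenness)

    def test_planted_modules_beat_rewired_null(self):
        """A modular network has higher mean Q than a weight-shuffled null."""
        rng = np.random.default_rng(15)
        w = np.zeros((12, 12))
        labels = np.repeat([0, 1], 6)
        for i in range(12):
            for j in range(i + 1, 12):
                p = 0.8 if labels[i] == labels[j] else 0.1
                if rng.random() < p:
                    w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
        iu, ju = np.triu_indices(12, 1)
        vals = w[iu, ju]
        shuffled = np.zeros_like(w)
        perm = rng.permutation(vals.size)
        shuffled[iu, ju] = vals[perm]
        shuffled += shuffled.T
        q_mod, _, _ = modularity_repeated(w, n_runs=50, rng=np.random.default_rng(4))
        q_null, _, _ = modularity_repeated(shuffled, n_runs=50, rng=np.random.default_rng(4))
        assert q_mod > q_null


class TestScaleProperties:
    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_uniform_weight_scaling(self, c):
        rng = np.random.default_rng(16)
        w = random_weighted_graph(12, 0.4, rng)
        net, net_c = as_net(w), as_net(c * w)
        np.testing.assert_allclose(node_degree(net_c), c * node_degree(net), atol=1e-12)
        e1, g1 = nodal_and_global_efficiency(shortest_paths(net))
        e2, g2 = nodal_and_global_efficiency(shortest_paths(net_c))
        np.testing.assert_allclose(e2, c * e1, atol=1e-10)
        assert g2 == pytest.approx(c * g1)
        # betweenness ranks unchanged; Q invariant
        b1, b2 = betweenness_centrality(net), betweenness_centrality(net_c)
        np.testing.assert_allclose(b1, b2, atol=1e-10)
        comm = np.arange(12) % 3
        assert modularity_q(w, comm) == pytest.approx(modularity_q(c * w, comm), abs=1e-12)

    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(17)
        w = random_weighted_graph(10, 0.3, rng)
        _, g1 = nodal_and_global_efficiency(shortest_paths(as_net(w)))
        empty = np.argwhere(np.triu(w == 0, 1))
        i, j = empty[rng.integers(len(empty))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
        _, g2 = nodal_and_global_efficiency(shortest_paths(as_net(w2)))
        assert g2 >= g1 - 1e-12
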