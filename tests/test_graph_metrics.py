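"""Weighted graph metrics vs hand calculations and independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from megconn.experiments import (
    brute_clustering,
    brute_floyd_warshall,
    brute_la,
    brute_paths_enumeration,
)
from megconn.graph_metrics import (
    clustering,
    metrics_record,
    node_degree,
    node_strength,
    path_length,
)
from megconn.io_core import ParameterError


def triangle(w12, w13, w23):
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = w12
    W[0, 2] = W[2, 0] = w13
    W[1, 2] = W[2, 1] = w23
    return W


def random_weighted_graph(rng, n, p=0.4):
    A = np.triu((rng.uniform(size=(n, n)) < p).astype(float), 1)
    W = A * rng.uniform(0.05, 1.0, size=(n, n))
    return W + W.T


def _wrap(W):
    from megconn.connectivity import WeightedGraph

    W = np.asarray(W, dtype=float)
    return WeightedGraph(
        nodes=tuple(f"n{i}" for i in range(W.shape[0])),
        W=W, K=3, band="t", subject_id="g", alpha=1.0, tp_crit=0.0,
    )


class TestStrength:
    def test_triangle_row_sums(self, make_graph):
        S, SA = node_strength(make_graph(triangle(0.5, 0.2, 0.3)))
        np.testing.assert_allclose(S, [0.7, 0.8, 0.5])
        assert SA == pytest.approx(2.0 / 3.0)

    def test_edgeless_graph_zero(self, make_graph):
        S, SA = node_strength(make_graph(np.zeros((4, 4))))
        assert SA == 0.0 and not S.any()

    def test_complete_unit_graph(self, make_graph):
        n = 5
        W = np.ones((n, n)) - np.eye(n)
        S, SA = node_strength(make_graph(W))
        np.testing.assert_allclose(S, n - 1)

    def test_negative_weights_enter_as_magnitudes(self, make_graph):
        S, _ = node_strength(make_graph(triangle(-0.5, 0.2, 0.3)))
        np.testing.assert_allclose(S, [0.7, 0.8, 0.5])


class TestDegree:
    def test_triangle(self, make_graph):
        d, DA = node_degree(make_graph(triangle(0.5, 0.2, 0.3)))
        np.testing.assert_array_equal(d, [2, 2, 2])
        assert DA == 2.0

    def test_path_graph(self, make_graph):
        d, DA = node_degree(make_graph(triangle(0.5, 0.0, 0.25)))
        assert DA == pytest.approx(4.0 / 3.0)

    @given(st.integers(0, 2**15 - 1))
    def test_handshake_identity(self, seed):
        # DA = 2K/N for any graph with K edges
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(rng, int(rng.integers(3, 9)))
        _, DA = node_degree(_wrap(W))
        n_edges = np.count_nonzero(np.triu(W, 1))
        assert DA == pytest.approx(2.0 * n_edges / W.shape[0])


class TestPathLength:
    def test_unit_triangle(self, make_graph):
        L, LA = path_length(make_graph(triangle(1.0, 1.0, 1.0)))
        np.testing.assert_allclose(L + np.eye(3), np.ones((3, 3)))
        assert LA == pytest.approx(1.0)

    def test_two_edge_chain_harmonic_mean(self, make_graph):
        # lengths 2 and 4 in series: L12=2, L23=4, L13=6 -> LA = 36/11
        L, LA = path_length(make_graph(triangle(0.5, 0.0, 0.25)))
        assert L[0, 1] == pytest.approx(2.0)
        assert L[1, 2] == pytest.approx(4.0)
        assert L[0, 2] == pytest.approx(6.0)
        assert LA == pytest.approx(36.0 / 11.0)

    def test_indirect_path_can_beat_direct_edge(self, make_graph):
        W = triangle(0.9, 0.1, 0.9)  # direct 0->2 length 10; via 1: 2/0.9
        L, _ = path_length(make_graph(W))
        assert L[0, 2] == pytest.approx(2.0 / 0.9)

    def test_fully_disconnected_is_infinite(self, make_graph):
        L, LA = path_length(make_graph(np.zeros((3, 3))))
        assert np.isinf(LA)
        assert np.isinf(L[0, 1])

    def test_single_node_rejected(self, make_graph):
        import megconn.connectivity as conn

        g = conn.WeightedGraph(nodes=("a",), W=np.zeros((1, 1)), K=3,
                               band="b", subject_id="s", alpha=1.0, tp_crit=0.0)
        with pytest.raises(ParameterError):
            path_length(g)


class TestClustering:
    def test_unit_triangle_fully_clustered(self, make_graph):
        C, CA = clustering(make_graph(triangle(1.0, 1.0, 1.0)))
        np.testing.assert_allclose(C, 1.0)
        assert CA == pytest.approx(1.0)

    def test_weighted_triangle_geometric_mean(self, make_graph):
        # ordered pairs double the (1,0.5,0.25) product's cube root:
        # C_i = 2*(0.125)^(1/3)/2 = 0.5 for every node after max-norm
        C, CA = clustering(make_graph(triangle(1.0, 0.5, 0.25)))
        np.testing.assert_allclose(C, 0.5)
        assert CA == pytest.approx(0.5)

    def test_star_graph_unclustered(self, make_graph):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 0.7
        C, CA = clustering(make_graph(W))
        assert CA == 0.0

    def test_scale_invariance_of_max_normalization(self, make_graph, rng):
        W = random_weighted_graph(rng, 7)
        C1, _ = clustering(make_graph(W))
        C2, _ = clustering(make_graph(W * 0.1))
        np.testing.assert_allclose(C1, C2, atol=1e-12)

    def test_binary_weights_reduce_to_unweighted_clustering(self, rng, make_graph):
        for seed in range(10):
            r = np.random.default_rng(seed)
            W = (random_weighted_graph(r, 8) > 0).astype(float)
            C, _ = clustering(make_graph(W))
            G = nx.from_numpy_array(W)
            expected = np.array([nx.clustering(G, i) for i in range(8)])
            np.testing.assert_allclose(C, expected, atol=1e-10)


class TestMetricsRecord:
    def test_complete_unit_k5(self, make_graph):
        W = np.ones((5, 5)) - np.eye(5)
        rec = metrics_record(make_graph(W))
        assert rec.SA == pytest.approx(4.0)
        assert rec.DA == pytest.approx(4.0)
        assert rec.LA == pytest.approx(1.0)
        assert rec.CA == pytest.approx(1.0)

    def test_permutation_invariance(self, make_graph, rng):
        W = random_weighted_graph(rng, 8)
        perm = rng.permutation(8)
        rec1 = metrics_record(make_graph(W))
        rec2 = metrics_record(make_graph(W[np.ix_(perm, perm)]))
        for name in ("SA", "DA", "LA", "CA"):
            a, b = rec1.scalars()[name], rec2.scalars()[name]
            if np.isinf(a):
                assert np.isinf(b)
            else:
                assert a == pytest.approx(b, abs=1e-10)

    def test_adding_edge_monotonicity(self, make_graph, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            W = random_weighted_graph(r, 7)
            zeros = np.argwhere(np.triu(W == 0, 1))
            if not len(zeros):
                continue
            i, j = zeros[r.integers(len(zeros))]
            W2 = W.copy()
            W2[i, j] = W2[j, i] = r.uniform(0.1, 1.0)
            rec1 = metrics_record(make_graph(W))
            rec2 = metrics_record(make_graph(W2))
            assert rec2.SA >= rec1.SA - 1e-12
            assert rec2.DA >= rec1.DA - 1e-12
            if np.isfinite(rec1.LA):
                assert rec2.LA <= rec1.LA + 1e-12

    def test_matches_independent_oracles_on_random_graphs(self, make_graph, rng):
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 9))
            W = random_weighted_graph(r, n)
            rec = metrics_record(make_graph(W))
            S, SA = (np.abs(W).sum(axis=1), np.abs(W).sum(axis=1).mean())
            np.testing.assert_allclose(rec.S, S, atol=1e-12)
            # shortest paths: exhaustive enumeration for small n
            L_ref = (brute_paths_enumeration(W) if n <= 6
                     else brute_floyd_warshall(W))
            finite = np.isfinite(L_ref)
            np.testing.assert_allclose(rec.L[finite], L_ref[finite], atol=1e-10)
            assert (np.isinf(rec.L) == np.isinf(L_ref)).all()
            la_ref = brute_la(L_ref)
            if np.isinf(la_ref):
                assert np.isinf(rec.LA)
            else:
                assert rec.LA == pytest.approx(la_ref, abs=1e-10)
            C_ref, CA_ref = brute_clustering(W)
            np.testing.assert_allclose(rec.C, C_ref, atol=1e-10)
            # cross-check shortest paths against networkx dijkstra as well
            G = nx.from_numpy_array(np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0))
            for i, j in itertools.combinations(range(n), 2):
                try:
                    d = nx.dijkstra_path_length(G, i, j, weight="weight")
                except nx.NetworkXNoPath:
                    d = np.inf
                if np.isinf(d):
                    assert np.isinf(rec.L[i, j])
                else:
                    assert rec.L[i, j] == pytest.approx(d, abs=1e-10)
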