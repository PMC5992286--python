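"""Global efficiency, OMST filtering, multilayer assembly, MPC, comodulograms."""

import numpy as np
import networkx as nx
import pytest

from mlfc.bands import coupling_modes
from mlfc.connectivity import SLFCG
from mlfc.graphs import (
    Comodulogram,
    assemble_mlfcg,
    comodulogram,
    global_efficiency,
    group_average_comodulogram,
    mpc,
    omst_filter,
)


def random_k5(rng):
    W = rng.uniform(0.1, 1.0, (5, 5))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


def nx_distance_graph(W):
    G = nx.Graph()
    n = W.shape[0]
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, weight=1.0 / W[i, j])
    return G


def nx_global_efficiency(W):
    """Independent GE oracle: networkx Dijkstra over 1/w distances."""
    G = nx_distance_graph(W)
    n = W.shape[0]
    total = 0.0
    for u in range(n):
        dist = nx.single_source_dijkstra_path_length(G, u)
        total += sum(1.0 / d for v, d in dist.items() if v != u)
    return total / (n * (n - 1))


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        W = np.ones((6, 6)) - np.eye(6)
        assert global_efficiency(W) == pytest.approx(1.0)

    def test_isolated_nodes(self):
        assert global_efficiency(np.zeros((2, 2))) == 0.0

    def test_path_graph_hand_value(self):
        """4-node unit path: pair distances {1,1,1,2,2,3} -> GE = 13/18."""
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        assert global_efficiency(W) == pytest.approx(13 / 18)

    def test_matches_networkx_oracle(self, rng):
        for _ in range(10):
            W = random_k5(rng)
            assert global_efficiency(W) == pytest.approx(nx_global_efficiency(W))


class TestOmst:
    def test_round1_is_classical_mst(self, rng):
        for _ in range(20):
            W = random_k5(rng)
            res = omst_filter(W)
            mst = nx.minimum_spanning_tree(nx_distance_graph(W))
            assert {frozenset(e) for e in res.selected_edges[0]} == {
                frozenset(e) for e in mst.edges()
            }
            assert len(res.selected_edges[0]) == 4

    def test_rounds_pairwise_disjoint(self, rng):
        W = rng.uniform(0.1, 1.0, (8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        res = omst_filter(W)
        flat = [e for r in res.selected_edges for e in r]
        assert len(flat) == len(set(flat))

    def test_cost_strictly_increases_and_j_consistent(self, rng):
        W = random_k5(rng)
        res = omst_filter(W)
        costs = [c for _, c in res.J_curve]
        assert all(b > a for a, b in zip(costs, costs[1:]))
        # J = GE - Cost, recomputed on reconstructed aggregates
        agg = np.zeros_like(W)
        for r, (J, cost) in enumerate(res.J_curve):
            for i, j in res.selected_edges[r]:
                agg[i, j] = agg[j, i] = W[i, j]
            assert J == pytest.approx(global_efficiency(agg) - cost)

    def test_ge_nondecreasing_over_rounds(self, rng):
        W = rng.uniform(0.1, 1.0, (8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        res = omst_filter(W)
        ges = [J + c for J, c in res.J_curve]
        assert all(b >= a - 1e-12 for a, b in zip(ges, ges[1:]))

    def test_tree_input_returned_whole(self):
        W = np.zeros((5, 5))
        for i in range(4):
            W[i, i + 1] = W[i + 1, i] = 0.5
        res = omst_filter(W)
        assert res.peak_round == 1
        assert np.array_equal(res.W_filtered, W)
        assert res.J_curve[0][1] == pytest.approx(1.0)  # the tree is the whole graph

    def test_disconnected_input_errors(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            omst_filter(W)

    def test_filtered_weights_are_original(self, rng):
        W = random_k5(rng)
        res = omst_filter(W)
        mask = res.W_filtered > 0
        assert np.allclose(res.W_filtered[mask], W[mask])


class TestMlfcg:
    @pytest.fixture()
    def layers(self, rng):
        out = []
        for m in coupling_modes():
            W = rng.uniform(0.0, 1.0, (10, 10))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            out.append(SLFCG("iplv", m, W))
        return out

    def test_flattened_layout(self, layers):
        ml = assemble_mlfcg(layers)
        assert ml.flattened.shape == (70, 70)
        assert np.allclose(ml.flattened, ml.flattened.T)
        # diagonal block b is the intra layer of band b, exactly
        assert np.array_equal(ml.flattened[:10, :10], layers[0].W)
        assert np.array_equal(ml.flattened[60:, 60:], layers[6].W)
        # first off-diagonal block is the delta:theta CFC layer
        assert np.array_equal(ml.flattened[:10, 10:20], layers[7].W)
        assert np.array_equal(ml.flattened[10:20, :10], layers[7].W.T)

    def test_wrong_layer_count_rejected(self, layers):
        with pytest.raises(ValueError, match="fixed-order"):
            assemble_mlfcg(layers[:27])

    def test_wrong_order_rejected(self, layers):
        shuffled = [layers[1], layers[0]] + layers[2:]
        with pytest.raises(ValueError, match="fixed-order"):
            assemble_mlfcg(shuffled)


class TestMpc:
    def test_single_layer_concentration_is_zero(self):
        layers = [np.zeros((4, 4)) for _ in range(28)]
        layers[0][0, 1] = layers[0][1, 0] = 1.0
        layers[0][0, 2] = layers[0][2, 0] = 1.0
        assert mpc(layers).per_node[0] == pytest.approx(0.0)

    def test_uniform_spread_is_one(self):
        L = np.zeros((3, 3))
        L[0, 1] = L[1, 0] = 1.0
        assert mpc([L.copy() for _ in range(28)]).per_node[0] == pytest.approx(1.0)

    def test_two_layer_hand_case(self):
        """M=2 with degrees (3,1): NLP = (0.75, 0.25), so
        MPC = 2 (1 - 0.5625 - 0.0625) = 0.75."""
        L1 = np.zeros((5, 5))
        for j in (1, 2, 3):
            L1[0, j] = L1[j, 0] = 1.0
        L2 = np.zeros((5, 5))
        L2[0, 4] = L2[4, 0] = 1.0
        assert mpc([L1, L2]).per_node[0] == pytest.approx(0.75)

    def test_isolated_node_zero(self):
        layers = [np.zeros((3, 3)) for _ in range(5)]
        layers[0][0, 1] = layers[0][1, 0] = 1.0
        res = mpc(layers)
        assert res.per_node[2] == 0.0
        assert res.global_mpc == pytest.approx(res.per_node.mean())

    def test_layer_permutation_invariance(self, rng):
        layers = [np.triu((rng.random((6, 6)) > 0.5).astype(float), 1) for _ in range(8)]
        layers = [L + L.T for L in layers]
        base = mpc(layers).per_node
        perm = [layers[i] for i in rng.permutation(8)]
        assert np.allclose(mpc(perm).per_node, base)

    def test_weight_scaling_invariance(self, rng):
        layers = [np.triu(rng.random((6, 6)), 1) for _ in range(5)]
        layers = [L + L.T for L in layers]
        sparse = [L * (L > 0.6) for L in layers]
        assert np.allclose(mpc(sparse).per_node, mpc([10 * L for L in sparse]).per_node)

    def test_dense_layers_warn(self):
        dense = [np.ones((4, 4)) - np.eye(4) for _ in range(3)]
        with pytest.warns(UserWarning, match="dense"):
            mpc(dense)

    def test_bounds(self, rng):
        layers = [np.triu((rng.random((8, 8)) > 0.5).astype(float), 1) for _ in range(28)]
        layers = [L + L.T for L in layers]
        res = mpc(layers)
        assert np.all(res.per_node >= 0) and np.all(res.per_node <= 1 + 1e-12)


class TestComodulogram:
    def test_all_edges_in_one_block(self):
        n, B = 5, 7
        W = np.zeros((B * n, B * n))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        cm = comodulogram(W, n, [f"b{i}" for i in range(B)])
        assert cm.PD[0, 0] == pytest.approx(1.0)
        assert cm.PD.sum() == pytest.approx(1.0)

    def test_normalization_and_layout(self, rng):
        n, B = 6, 7
        W = np.triu((rng.random((B * n, B * n)) > 0.8).astype(float), 1)
        W = W + W.T
        cm = comodulogram(W, n, [f"b{i}" for i in range(B)])
        assert cm.PD.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.tril(cm.PD, -1) == 0)

    def test_zero_edges_error(self):
        with pytest.raises(ValueError, match="no selected edges"):
            comodulogram(np.zeros((14, 14)), 2, list("abcdefg"))

    def test_group_average(self):
        names = tuple(f"b{i}" for i in range(7))
        a = Comodulogram(PD=np.eye(7) / 7, band_names=names)
        b = Comodulogram(PD=np.zeros((7, 7)), band_names=names)
        b.PD[0, 6] = 1.0
        avg = group_average_comodulogram([a, b])
        assert avg.PD.sum() == pytest.approx(1.0)
        assert avg.PD[0, 6] == pytest.approx(0.5)
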