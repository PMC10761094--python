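"""Bipartite edge-type message passing against brute-force oracles."""

import numpy as np
import pytest

from adagcn.autodiff import Tensor
from adagcn.dataset_io import AssociationMatrix
from adagcn.synthetic_data import toy_fixture
from adagcn.topology_gcn import (TopologyGcnParams, _type0_aggregate,
                                 build_topology_graph, dense_transform,
                                 init_topology_gcn_params,
                                 message_passing_forward)


def one_round_oracle(a1: np.ndarray, drug_tables: dict, dis_tables: dict):
    """Definitional oracle: explicit double loop over every pair and
    channel, messages (1/c_ij) x_j with c_ij = sqrt(|N_t(r_i)| |N_t(d_j)|)."""
    n, m = a1.shape
    h = dis_tables[1].shape[1]
    adj = {1: a1, 0: 1 - a1}
    h_r = np.zeros((n, h))
    h_d = np.zeros((m, h))
    for t in (1, 0):
        dr = adj[t].sum(axis=1)
        dd = adj[t].sum(axis=0)
        for i in range(n):
            for j in range(m):
                if adj[t][i, j]:
                    c = np.sqrt(dr[i] * dd[j])
                    h_r[i] += dis_tables[t][j] / c
                    h_d[j] += drug_tables[t][i] / c
    return np.tanh(h_r), np.tanh(h_d)


def _params_from_tables(drug_tables, dis_tables, dense=None):
    h = dis_tables[1].shape[1]
    return TopologyGcnParams(
        drug_codes={t: Tensor(drug_tables[t]) for t in (1, 0)},
        disease_codes={t: Tensor(dis_tables[t]) for t in (1, 0)},
        round_weights=[],
        dense_weight=Tensor(dense if dense is not None else np.eye(h)),
    )


class TestGraphBuilding:
    def test_toy_edge_counts(self):
        _, _, assoc = toy_fixture()
        graph = build_topology_graph(assoc)
        assert graph.edge_counts() == {1: 3, 0: 3}

    def test_all_ones_matrix_allowed(self):
        graph = build_topology_graph(AssociationMatrix(np.ones((2, 2))))
        assert graph.edge_counts() == {1: 4, 0: 0}

    def test_masking_moves_pair_to_unknown_channel(self):
        _, _, assoc = toy_fixture()
        mask = np.ones((3, 2), dtype=bool)
        mask[0, 0] = False
        graph = build_topology_graph(assoc, mask)
        assert graph.edge_counts() == {1: 2, 0: 4}
        assert graph.a1[0, 0] == 0

    def test_empty_positive_channel_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_topology_graph(AssociationMatrix(np.zeros((2, 2))))

    def test_type_specific_degrees(self):
        _, _, assoc = toy_fixture()
        graph = build_topology_graph(assoc)
        np.testing.assert_array_equal(graph.drug_degree[1], [1, 2, 0])
        np.testing.assert_array_equal(graph.drug_degree[0], [1, 0, 2])
        np.testing.assert_array_equal(graph.disease_degree[1], [2, 1])


class TestMessagePassing:
    def test_hand_computed_two_neighbor_drug(self):
        # drug 0 linked to both diseases, each disease of type-1 degree 1;
        # c = sqrt(2*1); identity code tables => h = tanh(1/sqrt(2), 1/sqrt(2))
        a1 = np.array([[1, 1]], dtype=np.int8)
        graph = build_topology_graph(AssociationMatrix(a1))
        dis_tables = {1: np.eye(2), 0: np.zeros((2, 2))}
        drug_tables = {1: np.zeros((1, 2)), 0: np.zeros((1, 2))}
        params = _params_from_tables(drug_tables, dis_tables)
        h_r, _ = message_passing_forward(graph, params)
        expected = np.tanh(1 / np.sqrt(2))
        np.testing.assert_allclose(h_r.data, [[expected, expected]], atol=1e-12)
        assert expected == pytest.approx(0.6089, abs=5e-4)

    def test_zero_weights_give_zero_hidden(self):
        _, _, assoc = toy_fixture()
        graph = build_topology_graph(assoc)
        zeros = {1: np.zeros((3, 4)), 0: np.zeros((3, 4))}
        zeros_d = {1: np.zeros((2, 4)), 0: np.zeros((2, 4))}
        params = _params_from_tables(zeros, zeros_d, dense=np.eye(4))
        h_r, h_d = message_passing_forward(graph, params)
        np.testing.assert_array_equal(h_r.data, np.zeros((3, 4)))
        np.testing.assert_array_equal(h_d.data, np.zeros((2, 4)))

    def test_one_round_matches_double_loop_oracle(self, rng):
        a1 = (rng.random((5, 4)) < 0.4).astype(np.int8)
        a1[0, 0] = 1  # ensure a positive exists
        graph = build_topology_graph(AssociationMatrix(a1))
        drug_tables = {t: rng.standard_normal((5, 3)) for t in (1, 0)}
        dis_tables = {t: rng.standard_normal((4, 3)) for t in (1, 0)}
        params = _params_from_tables(drug_tables, dis_tables, dense=np.eye(3))
        h_r, h_d = message_passing_forward(graph, params)
        exp_r, exp_d = one_round_oracle(a1, drug_tables, dis_tables)
        np.testing.assert_allclose(h_r.data, exp_r, atol=1e-10)
        np.testing.assert_allclose(h_d.data, exp_d, atol=1e-10)

    @pytest.mark.parametrize("shape", [(6, 5), (20, 20)])
    def test_complement_shortcut_matches_explicit_loop(self, shape, rng):
        n, m = shape
        a1 = (rng.random((n, m)) < 0.3).astype(np.int8)
        features = rng.standard_normal((m, 4))
        dr0 = (m - a1.sum(axis=1)).astype(float)
        dd0 = (n - a1.sum(axis=0)).astype(float)
        inv = lambda x: np.where(x > 0, 1 / np.sqrt(np.maximum(x, 1)), 0.0)
        got = _type0_aggregate(a1, inv(dr0), inv(dd0), Tensor(features)).data
        expected = np.zeros((n, 4))
        for i in range(n):
            for j in range(m):
                if a1[i, j] == 0 and dr0[i] > 0 and dd0[j] > 0:
                    expected[i] += features[j] / np.sqrt(dr0[i] * dd0[j])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_tanh_bounds_and_determinism(self, rng):
        a1 = (rng.random((8, 6)) < 0.3).astype(np.int8)
        a1[0, 0] = 1
        graph = build_topology_graph(AssociationMatrix(a1))
        params = init_topology_gcn_params(8, 6, 5, 2, np.random.default_rng(0))
        h_r, h_d = message_passing_forward(graph, params)
        h_r2, _ = message_passing_forward(graph, params)
        assert (np.abs(h_r.data) < 1).all() and (np.abs(h_d.data) < 1).all()
        np.testing.assert_array_equal(h_r.data, h_r2.data)

    def test_permutation_equivariance(self, rng):
        n, m = 6, 5
        a1 = (rng.random((n, m)) < 0.4).astype(np.int8)
        a1[0, 0] = 1
        drug_tables = {t: rng.standard_normal((n, 3)) for t in (1, 0)}
        dis_tables = {t: rng.standard_normal((m, 3)) for t in (1, 0)}
        graph = build_topology_graph(AssociationMatrix(a1))
        h_r, h_d = message_passing_forward(
            graph, _params_from_tables(drug_tables, dis_tables, np.eye(3)))

        perm = rng.permutation(n)
        graph_p = build_topology_graph(AssociationMatrix(a1[perm]))
        params_p = _params_from_tables(
            {t: drug_tables[t][perm] for t in (1, 0)}, dis_tables, np.eye(3))
        h_r_p, h_d_p = message_passing_forward(graph_p, params_p)
        np.testing.assert_allclose(h_r_p.data, h_r.data[perm], atol=1e-10)
        np.testing.assert_allclose(h_d_p.data, h_d.data, atol=1e-10)


class TestDenseTransform:
    def test_identity_weight(self, rng):
        hidden = Tensor(rng.standard_normal((4, 3)))
        params = _params_from_tables({1: np.zeros((4, 3)), 0: np.zeros((4, 3))},
                                     {1: np.zeros((2, 3)), 0: np.zeros((2, 3))},
                                     dense=np.eye(3))
        np.testing.assert_array_equal(dense_transform(hidden, params).data,
                                      hidden.data)

    def test_zero_weight(self, rng):
        hidden = Tensor(rng.standard_normal((4, 3)))
        params = _params_from_tables({1: np.zeros((4, 3)), 0: np.zeros((4, 3))},
                                     {1: np.zeros((2, 3)), 0: np.zeros((2, 3))},
                                     dense=np.zeros((3, 3)))
        np.testing.assert_array_equal(dense_transform(hidden, params).data,
                                      np.zeros((4, 3)))

    def test_matches_matrix_product(self, rng):
        hidden = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 3))
        params = _params_from_tables({1: np.zeros((5, 3)), 0: np.zeros((5, 3))},
                                     {1: np.zeros((2, 3)), 0: np.zeros((2, 3))},
                                     dense=w)
        np.testing.assert_allclose(dense_transform(Tensor(hidden), params).data,
                                   hidden @ w, atol=1e-12)
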