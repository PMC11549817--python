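import math

import numpy as np
import pytest

from modprio import (
    AssociationSet,
    FeatureTable,
    GeneGraph,
    GnnConfig,
    GnnParams,
    ModuleSet,
    build_network,
    forward,
    gat_layer,
    gcn_layer,
    sage_layer,
)
from modprio.autodiff import Tensor
from modprio.hetero_gnn import forward_tensor

from .oracles import gat_dense, gcn_dense, sage_dense


def _features(ids, X):
    return FeatureTable(ids=list(ids), X=np.asarray(X, dtype=float))


def _single_head_params(W, a, in_dim, out_dim):
    cfg = GnnConfig(in_dim=in_dim, gat_out=out_dim, heads=1, hidden=(2, 2))
    p = GnnParams.init(cfg, seed=0)
    p.gat_heads = [(Tensor(np.asarray(W, float), requires_grad=True),
                    Tensor(np.asarray(a, float).reshape(-1, 1), requires_grad=True))]
    return p


class TestGatLayer:
    def test_single_neighbor_attention_is_identity_weighting(self):
        """With one neighbor, softmax gives alpha = 1 and H_i' = W H_j."""
        W = [[2.0, 0.0], [0.0, 3.0]]
        a = [0.5, -0.2, 0.1, 0.4]
        feats = _features(["i", "j"], [[1.0, 1.0], [2.0, -1.0]])
        params = _single_head_params(W, a, 2, 2)
        out = gat_layer(feats, {("i", "j")}, params)
        np.testing.assert_allclose(out.X[0], np.array(W) @ [2.0, -1.0])  # W H_j
        np.testing.assert_allclose(out.X[1], np.array(W) @ [1.0, 1.0])

    def test_two_identical_neighbors_split_attention_equally(self):
        W = np.eye(2)
        a = [1.0, 1.0, -1.0, 0.5]
        feats = _features(["i", "j", "k"], [[0.0, 1.0], [3.0, 5.0], [3.0, 5.0]])
        params = _single_head_params(W, a, 2, 2)
        out = gat_layer(feats, {("i", "j"), ("i", "k")}, params)
        # alpha = (1/2, 1/2) over two identical neighbors
        np.testing.assert_allclose(out.X[0], [3.0, 5.0])

    def test_matches_dense_oracle_on_toy_graph(self):
        rng = np.random.default_rng(5)
        ids = ["a", "b", "c", "d"]
        X = rng.standard_normal((4, 3))
        edges = {("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")}
        cfg = GnnConfig(in_dim=3, gat_out=2, heads=2, hidden=(2, 2))
        params = GnnParams.init(cfg, seed=1)
        out = gat_layer(_features(ids, X), edges, params)
        idx = {n: i for i, n in enumerate(ids)}
        adj = {}
        for u, v in edges:
            adj.setdefault(idx[u], set()).add(idx[v])
            adj.setdefault(idx[v], set()).add(idx[u])
        heads = [(W.data, a.data) for W, a in params.gat_heads]
        np.testing.assert_allclose(out.X, gat_dense(X, adj, heads), atol=1e-5)

    def test_isolated_node_self_fallback(self):
        W = np.eye(2) * 2
        params = _single_head_params(W, [1, 0, 0, 1], 2, 2)
        out = gat_layer(_features(["z"], [[0.5, 0.5]]), set(), params)
        np.testing.assert_allclose(out.X[0], [1.0, 1.0])  # alpha_zz = 1, W H_z


class TestGcnLayer:
    def test_two_gene_chain_forced_value(self):
        """i-j with unit degrees: H_i' = ReLU(1 * 1 * 2) = 2."""
        feats = _features(["i", "j"], [[1.0], [1.0]])
        out = gcn_layer(feats, {("i", "j")}, Tensor([[2.0]]), Tensor([0.0]))
        np.testing.assert_allclose(out.X, [[2.0], [2.0]])

    def test_relu_clips_negative_bias(self):
        feats = _features(["i", "j"], [[1.0], [1.0]])
        out = gcn_layer(feats, {("i", "j")}, Tensor([[0.0]]), Tensor([-1.0]))
        np.testing.assert_allclose(out.X, [[0.0], [0.0]])

    def test_isolated_node_outputs_relu_bias(self):
        feats = _features(["i", "j", "z"], [[1.0], [1.0], [5.0]])
        out = gcn_layer(feats, {("i", "j")}, Tensor([[1.0]]), Tensor([0.7]))
        assert out.X[2, 0] == pytest.approx(0.7)

    def test_matches_dense_normalized_adjacency_oracle(self):
        rng = np.random.default_rng(6)
        n = 10
        ids = [f"n{i}" for i in range(n)]
        A = np.zeros((n, n))
        edges = set()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    edges.add((ids[i], ids[j]))
                    A[i, j] = A[j, i] = 1.0
        X = rng.standard_normal((n, 4))
        W = rng.standard_normal((4, 3))
        b = rng.standard_normal(3)
        out = gcn_layer(_features(ids, X), edges, Tensor(W), Tensor(b))
        np.testing.assert_allclose(out.X, gcn_dense(X, A, W, b), atol=1e-5)


class TestSageLayer:
    def test_full_sampling_single_neighbor(self):
        """fraction=1 and one neighbor: ReLU(W [H_i || H_j])."""
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.arange(8.0).reshape(4, 2)
        out = sage_layer(_features(["i", "j"], X), {("i", "j")}, Tensor(W))
        expect_i = np.maximum(np.concatenate([X[0], X[1]]) @ W, 0)
        np.testing.assert_allclose(out.X[0], expect_i)

    def test_identical_neighbors_mean_invariant_to_sample(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        W = np.eye(4)[:, :2]
        edges = {("i", "a"), ("i", "b"), ("i", "c")}
        for frac, seed in [(1.0, 0), (0.34, 1), (0.67, 2)]:
            out = sage_layer(
                _features(["i", "a", "b", "c"], X), edges, Tensor(W),
                sample_fraction=frac, seed=seed,
            )
            np.testing.assert_allclose(out.X[0], [0.0, 0.0])

    def test_no_edges_aggregates_zero_vector(self):
        X = np.array([[1.0, -1.0]])
        W = np.ones((4, 2))
        out = sage_layer(_features(["i"], X), set(), Tensor(W))
        expect = np.maximum(np.concatenate([X[0], [0, 0]]) @ W, 0)
        np.testing.assert_allclose(out.X[0], expect)

    def test_seeded_sampling_matches_scripted_oracle(self):
        rng = np.random.default_rng(7)
        ids = ["i"] + [f"n{k}" for k in range(6)]
        X = rng.standard_normal((7, 3))
        W = rng.standard_normal((6, 4))
        edges = {("i", f"n{k}") for k in range(6)}
        seed, frac = 13, 0.5
        out = sage_layer(_features(ids, X), edges, Tensor(W),
                         sample_fraction=frac, seed=seed)
        # scripted reimplementation of the documented sampling procedure:
        # per node in index order, choose ceil(frac * deg) neighbors without
        # replacement from the same seeded generator
        from modprio.hetero_gnn import _directed_arrays, _sample_neighbors
        index = {n: i for i, n in enumerate(ids)}
        src, dst = _directed_arrays(edges, index)
        s, d = _sample_neighbors(src, dst, 7, frac, np.random.default_rng(seed))
        sets: dict[int, list[int]] = {}
        for j, i in zip(s, d):
            sets.setdefault(int(i), []).append(int(j))
        assert len(sets[0]) == math.ceil(frac * 6)
        np.testing.assert_allclose(out.X, sage_dense(X, sets, W), atol=1e-6)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sage_layer(_features(["i"], [[1.0]]), set(), Tensor(np.ones((2, 1))),
                       sample_fraction=0.0)


def _toy_net(seed=0, with_assoc=True):
    rng = np.random.default_rng(seed)
    g = GeneGraph()
    genes = [f"g{i}" for i in range(6)]
    for i in range(6):
        for j in range(i + 1, 6):
            if rng.random() < 0.5:
                g.add_edge(genes[i], genes[j])
    assoc = {("d0", "g0"), ("d0", "g3"), ("d1", "g2")} if with_assoc else set()
    net = build_network(g, AssociationSet(assoc), ModuleSet({}))
    ids = sorted(net.all_nodes)
    X = rng.standard_normal((len(ids), 4))
    return net, ids, X


class TestForward:
    def _params(self):
        cfg = GnnConfig(in_dim=4, gat_out=3, heads=2, hidden=(3, 2))
        return GnnParams.init(cfg, seed=2)

    def test_outputs_finite_without_association_edges(self):
        net, ids, X = _toy_net(with_assoc=False)
        emb = forward(net, FeatureTable(ids, X), self._params(),
                      {n: X[i] for i, n in enumerate(ids)})
        assert np.isfinite(emb.H).all()
        assert emb.H_tilde.shape[1] == emb.H.shape[1] + X.shape[1]

    def test_permutation_equivariance(self):
        net, ids, X = _toy_net(seed=3)
        params = self._params()
        node_vecs = {n: X[i] for i, n in enumerate(ids)}
        emb1 = forward(net, FeatureTable(ids, X), params, node_vecs)
        perm = list(reversed(range(len(ids))))
        ids2 = [ids[i] for i in perm]
        X2 = X[perm]
        emb2 = forward(net, FeatureTable(ids2, X2), params,
                       {n: node_vecs[n] for n in ids2})
        for n in ids:
            np.testing.assert_allclose(
                emb1.H[emb1.ids.index(n)], emb2.H[emb2.ids.index(n)], atol=1e-8
            )

    def test_degree_regular_identical_features_give_identical_outputs(self):
        g = GeneGraph()
        cyc = [f"g{i}" for i in range(6)]
        for i in range(6):
            g.add_edge(cyc[i], cyc[(i + 1) % 6])
        net = build_network(g, AssociationSet(set()), ModuleSet({}))
        ids = sorted(net.all_nodes)
        X = np.tile([1.0, -0.5, 0.25, 2.0], (6, 1))
        emb = forward(net, FeatureTable(ids, X), self._params(),
                      {n: X[0] for n in ids})
        np.testing.assert_allclose(emb.H, np.tile(emb.H[0], (6, 1)), atol=1e-9)

    def test_output_rows_unit_norm_by_default(self):
        net, ids, X = _toy_net(seed=4)
        _, H = forward_tensor(net, FeatureTable(ids, X), self._params(), seed=0)
        np.testing.assert_allclose(np.linalg.norm(H.data, axis=1), 1.0, atol=1e-5)

    def test_config_shape_validation(self):
        with pytest.raises(ValueError):
            GnnConfig(in_dim=4, sample_fraction=1.5)
        with pytest.raises(ValueError):
            GnnConfig(in_dim=0)
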