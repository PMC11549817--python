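import itertools

import numpy as np
import pytest

from modprio import (
    AssociationSet,
    EmbeddingTable,
    GeneGraph,
    ModuleSet,
    build_network,
    generate_candidates,
    generate_walks,
    moduleize,
    train_embeddings,
)
from modprio.skipgram import train_skipgram


def _net_from_edges(edges, assoc=(), modules=None, extra_nodes=()):
    g = GeneGraph(nodes=set(extra_nodes))
    for e in edges:
        g.add_edge(*e)
    return build_network(
        g, AssociationSet(set(assoc)), ModuleSet(modules or {})
    )


def _cos(a, b):
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


class TestGenerateWalks:
    def test_isolated_node_gives_singletons(self):
        net = _net_from_edges([], extra_nodes=["g1"])
        walks = generate_walks(net, num_walks=4, walk_length=10, seed=0)
        assert walks == [["g1"]] * 4

    def test_two_node_graph_alternates(self):
        net = _net_from_edges([("a", "b")])
        walks = generate_walks(net, num_walks=2, walk_length=4, seed=0)
        assert sorted(walks)[0] == ["a", "b", "a", "b"]
        assert all(len(w) == 4 for w in walks)

    def test_walk_count_and_length(self, toy_network):
        walks = generate_walks(toy_network, num_walks=3, walk_length=8, seed=1)
        assert len(walks) == 3 * len(toy_network.all_nodes)
        assert all(len(w) <= 8 for w in walks)

    def test_reproducible_per_seed(self, toy_network):
        w1 = generate_walks(toy_network, num_walks=2, walk_length=6, seed=5)
        w2 = generate_walks(toy_network, num_walks=2, walk_length=6, seed=5)
        assert w1 == w2

    def test_invalid_bias_parameters(self, toy_network):
        with pytest.raises(ValueError):
            generate_walks(toy_network, p_return=0.0)
        with pytest.raises(ValueError):
            generate_walks(toy_network, q_inout=-1.0)

    def test_second_order_bias_matches_transition_formula(self):
        """On a 4-cycle a-b-c-d, the step after (a, b) goes to c with
        probability (1/q) / (1/p + 1/q): c is an outward node, a the return."""
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        p_return, q_inout = 1.0, 0.3
        walks = generate_walks(
            net, num_walks=4000, walk_length=3,
            p_return=p_return, q_inout=q_inout, seed=11,
        )
        outward = back = 0
        for w in walks:
            for t in range(len(w) - 2):
                prev, cur, nxt = w[t], w[t + 1], w[t + 2]
                if {prev, cur} == {"a", "b"}:
                    if nxt == prev:
                        back += 1
                    else:
                        outward += 1
        n = outward + back
        expect = (1 / q_inout) / (1 / p_return + 1 / q_inout)
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(outward / n - expect) < 3 * sigma


class TestModuleize:
    def test_gene_tokens_replaced_by_module_id(self):
        modules = ModuleSet({"M1": {"g1", "g3"}})
        out = moduleize([["g1", "g3", "g5", "d3"]], modules)
        assert out == [["M1", "M1", "g5", "d3"]]

    def test_identity_without_module_members(self):
        modules = ModuleSet({"M1": {"g9"}})
        walks = [["g1", "d1", "g2"]]
        assert moduleize(walks, modules) == walks

    def test_multi_module_gene_uses_fixed_assignment(self):
        modules = ModuleSet({"M1": {"g"}, "M2": {"g"}})
        out = moduleize([["g", "x", "g"]], modules, assignment={"g": "M2"})
        assert out == [["M2", "x", "M2"]]
        # default assignment: lexicographically smallest module id
        assert moduleize([["g"]], modules) == [["M1"]]

    def test_length_preserving(self):
        modules = ModuleSet({"M1": {"g1"}})
        walks = [["g1"] * k for k in (1, 3, 7)]
        assert [len(w) for w in moduleize(walks, modules)] == [1, 3, 7]


class TestTrainEmbeddings:
    def test_dimensions_uniform(self):
        walks = [["a", "b", "c", "a"], ["b", "c", "a", "b"]]
        emb = train_embeddings(walks, walks, {}, dim=16, window=2, epochs=1, seed=0)
        assert all(v.shape == (16,) for v in emb.node_vectors.values())
        assert emb.dim == 16

    def test_moduleless_gene_module_vector_equals_node_vector(self):
        walks = [["a", "b", "c", "a"], ["c", "a", "b", "c"]]
        mod_walks = moduleize(walks, ModuleSet({"M1": {"a"}}))
        emb = train_embeddings(
            walks, mod_walks, {"a": "M1"}, dim=8, window=2, epochs=1, seed=0
        )
        assert np.array_equal(emb.node_vectors["b"], emb.module_vectors["b"])
        assert not np.array_equal(emb.node_vectors["a"], emb.module_vectors["a"])

    def test_deterministic_per_seed(self):
        walks = [["a", "b", "c", "d"], ["d", "c", "b", "a"]]
        e1 = train_embeddings(walks, walks, {}, dim=8, window=2, epochs=2, seed=3)
        e2 = train_embeddings(walks, walks, {}, dim=8, window=2, epochs=2, seed=3)
        for n in e1.node_vectors:
            assert np.array_equal(e1.node_vectors[n], e2.node_vectors[n])

    def test_barbell_cliques_have_locality_structure(self):
        """Skip-gram on walks separates two cliques joined by one edge."""
        g = GeneGraph()
        left = [f"a{i}" for i in range(5)]
        right = [f"b{i}" for i in range(5)]
        for side in (left, right):
            for x, y in itertools.combinations(side, 2):
                g.add_edge(x, y)
        g.add_edge(left[0], right[0])
        net = build_network(g, AssociationSet(set()), ModuleSet({}))
        walks = generate_walks(net, num_walks=20, walk_length=10, seed=2)
        vec = train_skipgram(walks, dim=16, window=3, epochs=8, seed=2)
        within = [
            _cos(vec[x], vec[y])
            for side in (left, right)
            for x, y in itertools.combinations(side, 2)
        ]
        across = [_cos(vec[x], vec[y]) for x in left for y in right]
        assert np.mean(within) > np.mean(across)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_skipgram([], dim=4)


class TestGenerateCandidates:
    def _table(self, vectors):
        return EmbeddingTable(
            {k: np.asarray(v, dtype=float) for k, v in vectors.items()},
            {k: np.asarray(v, dtype=float) for k, v in vectors.items()},
        )

    def test_identical_vector_ranks_first_with_similarity_one(self):
        net = _net_from_edges([("g1", "g2")], assoc=[("d1", "g2")])
        emb = self._table({"d1": [1, 0], "g1": [1, 0], "g2": [0, 1]})
        cands = generate_candidates(emb, net, k=5)
        assert cands.per_disease["d1"][0] == ("g1", pytest.approx(1.0))

    def test_training_genes_excluded(self):
        net = _net_from_edges([("g1", "g2")], assoc=[("d1", "g1")])
        emb = self._table({"d1": [1, 0], "g1": [1, 0], "g2": [1, 1]})
        assert "g1" not in cands_genes(generate_candidates(emb, net, k=5), "d1")

    def test_k_larger_than_gene_count_returns_all_eligible(self):
        net = _net_from_edges([("g1", "g2"), ("g2", "g3")], assoc=[("d1", "g1")])
        cands = generate_candidates(
            self._table({"d1": [1, 1], "g1": [1, 0], "g2": [0, 1], "g3": [1, 1]}),
            net,
            k=99,
        )
        assert cands_genes(cands, "d1") == ["g3", "g2"]

    def test_zero_norm_vector_similarity_zero(self):
        net = _net_from_edges([("g1", "g2")], assoc=[("d1", "g2")])
        emb = self._table({"d1": [0, 0], "g1": [1, 0], "g2": [0, 1]})
        with pytest.warns(UserWarning, match="zero-norm"):
            cands = generate_candidates(emb, net, k=5)
        assert cands.per_disease["d1"][0][1] == 0.0

    def test_matches_exhaustive_cosine_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:02d}" for i in range(20)]
        vecs = {g: rng.standard_normal(6) for g in genes}
        vecs["d1"] = rng.standard_normal(6)
        net = _net_from_edges(
            [(genes[i], genes[i + 1]) for i in range(19)], assoc=[("d1", genes[0])]
        )
        cands = generate_candidates(self._table(vecs), net, k=7)
        expected = sorted(
            (
                (g, _cos(vecs["d1"], vecs[g]))
                for g in genes
                if g != genes[0]
            ),
            key=lambda t: (-t[1], t[0]),
        )[:7]
        got = cands.per_disease["d1"]
        assert [g for g, _ in got] == [g for g, _ in expected]
        assert [s for _, s in got] == pytest.approx([s for _, s in expected])


def cands_genes(cands, disease):
    return [g for g, _ in cands.per_disease[disease]]
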