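"""Module-aware graph embedding and candidate generation.

Second-order biased random walks (node2vec style) over the heterogeneous
module network produce, for each start node, a conventional node sequence;
substituting each gene token by the id of its protein complex yields a
parallel module sequence. Training skip-gram separately on the two corpora
gives every node both a node embedding and a module embedding; a node in no
module reuses its node embedding as its module embedding. Cosine similarity
between a disease's node embedding and all gene embeddings then pre-filters
each disease to its top-k candidate genes, so the trained scorer only ever
ranks a short list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_model import HeteroModuleNetwork, ModuleSet
from .skipgram import train_skipgram


@dataclass
class WalkCorpus:
    """Paired node sequences and their module-substituted counterparts."""

    node_walks: list[list[str]]
    module_walks: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.node_walks) != len(self.module_walks):
            raise ValueError("corpora must pair 1:1")


@dataclass
class EmbeddingTable:
    """Node and module embeddings, both covering every node of the network."""

    node_vectors: dict[str, np.ndarray]
    module_vectors: dict[str, np.ndarray]

    @property
    def dim(self) -> int:
        return len(next(iter(self.node_vectors.values())))

    def feature(self, node: str) -> np.ndarray:
        """Initial GNN feature H^0 = [node embedding || module embedding]."""
        return np.concatenate([self.node_vectors[node], self.module_vectors[node]])


@dataclass
class CandidateSet:
    """Per-disease candidate genes with cosine similarities, best first."""

    per_disease: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def genes_for(self, disease: str) -> list[str]:
        return [g for g, _ in self.per_disease.get(disease, [])]


def generate_walks(
    net: HeteroModuleNetwork,
    num_walks: int = 10,
    walk_length: int = 64,
    p_return: float = 1.0,
    q_inout: float = 0.3,
    seed: int = 0,
) -> list[list[str]]:
    """Second-order biased random walks from every node of the network.

    Transition weights relative to the previous step's node t: 1/p_return to
    return to t, 1 to a common neighbor of t and the current node, 1/q_inout
    to an outward node. Walks stop early only at nodes with no neighbors;
    `walk_length` counts tokens including the start.
    """
    if p_return <= 0 or q_inout <= 0:
        raise ValueError("p_return and q_inout must be positive")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    adj = net.hetero_adjacency()
    nbrs = {n: sorted(ns) for n, ns in adj.items()}
    rng = np.random.default_rng(seed)
    walks: list[list[str]] = []
    for start in sorted(net.all_nodes):
        for _ in range(num_walks):
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                cand = nbrs[cur]
                if not cand:
                    break
                if len(walk) == 1:
                    nxt = cand[rng.integers(len(cand))]
                else:
                    prev = walk[-2]
                    prev_nbrs = adj[prev]
                    w = np.empty(len(cand))
                    for i, x in enumerate(cand):
                        if x == prev:
                            w[i] = 1.0 / p_return
                        elif x in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q_inout
                    w /= w.sum()
                    nxt = cand[rng.choice(len(cand), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return walks


def moduleize(
    walks: list[list[str]],
    modules: ModuleSet,
    assignment: dict[str, str] | None = None,
) -> list[list[str]]:
    """Replace each gene token that belongs to a complex by its module id.

    Tokens without a module (including all disease tokens) pass through
    unchanged; output sequences align 1:1 with the input. `assignment` fixes
    the module of multi-module genes (default: lexicographically smallest
    module id, via :meth:`ModuleSet.assignment`).
    """
    if assignment is None:
        assignment = modules.assignment()
    return [[assignment.get(tok, tok) for tok in walk] for walk in walks]


def build_corpus(
    net: HeteroModuleNetwork,
    num_walks: int = 10,
    walk_length: int = 64,
    p_return: float = 1.0,
    q_inout: float = 0.3,
    seed: int = 0,
) -> WalkCorpus:
    """Generate the paired node/module walk corpora for a network."""
    node_walks = generate_walks(net, num_walks, walk_length, p_return, q_inout, seed)
    module_walks = moduleize(node_walks, net.modules)
    return WalkCorpus(node_walks, module_walks)


def train_embeddings(
    node_walks: list[list[str]],
    module_walks: list[list[str]],
    assignment: dict[str, str],
    dim: int = 128,
    window: int = 5,
    epochs: int = 10,
    negative: int = 5,
    seed: int = 0,
) -> EmbeddingTable:
    """Train skip-gram on both corpora and assemble the embedding table.

    The two corpora are embedded by two independent models. A gene assigned
    to module m receives m's vector from the module-corpus model as its
    module embedding; any node without a module keeps its node embedding as
    its module embedding.
    """
    node_vec = train_skipgram(node_walks, dim=dim, window=window, epochs=epochs,
                              negative=negative, seed=seed)
    if not assignment:
        # no module anywhere: every module embedding is the node embedding,
        # so the module corpus carries no extra information
        return EmbeddingTable(node_vectors=node_vec,
                              module_vectors={n: v for n, v in node_vec.items()})
    module_vec_raw = train_skipgram(module_walks, dim=dim, window=window,
                                    epochs=epochs, negative=negative, seed=seed + 1)
    module_vec: dict[str, np.ndarray] = {}
    for node, nv in node_vec.items():
        mid = assignment.get(node)
        if mid is None:
            module_vec[node] = nv
        elif mid in module_vec_raw:
            module_vec[node] = module_vec_raw[mid]
        else:
            warnings.warn(f"module token {mid!r} absent from corpus; zero vector")
            module_vec[node] = np.zeros(dim)
    return EmbeddingTable(node_vectors=node_vec, module_vectors=module_vec)


def _cosine_matrix(q: np.ndarray, M: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(q)
    Mn = np.linalg.norm(M, axis=1)
    if qn == 0 or np.any(Mn == 0):
        warnings.warn("zero-norm embedding encountered; similarity set to 0")
    denom = np.where(Mn * qn == 0, 1.0, Mn * qn)
    sims = (M @ q) / denom
    sims[Mn * qn == 0] = 0.0
    return sims


def generate_candidates(
    embeddings: EmbeddingTable, net: HeteroModuleNetwork, k: int = 100
) -> CandidateSet:
    """Top-k cosine-nearest genes per disease, excluding its training genes.

    Ties break on gene id ascending; a zero-norm vector yields similarity 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = sorted(net.gene_nodes)
    M = np.stack([embeddings.node_vectors[g] for g in genes])
    by_disease = net.associations.by_disease()
    out: dict[str, list[tuple[str, float]]] = {}
    for d in sorted(net.disease_nodes):
        sims = _cosine_matrix(embeddings.node_vectors[d], M)
        known = by_disease.get(d, set())
        scored = [(g, float(s)) for g, s in zip(genes, sims) if g not in known]
        scored.sort(key=lambda t: (-t[1], t[0]))
        out[d] = scored[:k]
    return CandidateSet(out)
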