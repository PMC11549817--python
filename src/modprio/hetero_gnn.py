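"""Heterogeneous graph neural network over the module network.

Architecture: a single multi-head graph-attention (GAT) layer over the full
heterogeneous graph assigns learned weights to all neighbors; from its
output, two graph-convolution (GCN) layers run on the gene-gene subgraph in
parallel with two sampled-aggregation (GraphSAGE, mean aggregator) layers on
the disease-gene subgraph, and the two branch outputs are summed elementwise
per node. The GCN branch is defined on gene nodes only, so disease nodes
receive the SAGE branch alone (equivalently, a zero GCN contribution).

Equations implemented:
  GAT:  e_ij = LeakyReLU(a^T [W H_i || W H_j]),  alpha_ij = softmax_j(e_ij),
        H_i' = sum_j alpha_ij W H_j           (heads averaged)
  GCN:  H_i' = ReLU(sum_j H_j W / (sqrt(|N_j|) sqrt(|N_i|)) + b)
  SAGE: H_i' = ReLU(W [H_i || mean_{j in N_i'} H_j]),
        N_i' a seeded sample of ceil(fraction * |N_i|) neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather, segment_softmax, segment_sum
from .network_model import HeteroModuleNetwork


@dataclass
class GnnConfig:
    """Shapes and switches of the network.

    `gat_out` is the per-head (and, heads being averaged, overall) output
    width of the attention layer; the attention vector a then has length
    2 * gat_out. `hidden` gives the two successive widths of both the GCN
    and the SAGE branch, whose input width is `gat_out`.
    """

    in_dim: int
    gat_out: int = 128
    heads: int = 2
    hidden: tuple[int, int] = (64, 8)
    sample_fraction: float = 1.0
    gcn_self_loops: bool = False
    leaky_slope: float = 0.2
    #: row-wise L2 normalization of the aggregated output, as in the
    #: GraphSAGE convention; keeps |H| commensurate with the walk embedding
    #: it is concatenated with at scoring time and keeps cosine gradients
    #: from vanishing as |H| grows
    normalize_output: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.heads < 1 or self.gat_out < 1 or self.in_dim < 1:
            raise ValueError("dimensions must be positive")


@dataclass
class FeatureTable:
    """Per-node feature rows in a fixed id order."""

    ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("feature matrix rows must match ids")

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.ids)}

    def vector(self, node: str) -> np.ndarray:
        return self.X[self.ids.index(node)]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


@dataclass
class GnnParams:
    """All trainable tensors, shape-consistent with a GnnConfig."""

    config: GnnConfig
    gat_heads: list[tuple[Tensor, Tensor]] = field(default_factory=list)  # (W0, a)
    gcn: list[tuple[Tensor, Tensor]] = field(default_factory=list)        # (W, b)
    sage: list[Tensor] = field(default_factory=list)                      # W

    @classmethod
    def init(cls, config: GnnConfig, seed: int = 0) -> "GnnParams":
        rng = np.random.default_rng(seed)
        heads = [
            (
                Tensor(_glorot(rng, config.in_dim, config.gat_out), requires_grad=True),
                Tensor(_glorot(rng, 2 * config.gat_out, 1), requires_grad=True),
            )
            for _ in range(config.heads)
        ]
        h1, h2 = config.hidden
        gcn = [
            (
                Tensor(_glorot(rng, config.gat_out, h1), requires_grad=True),
                Tensor(np.zeros(h1), requires_grad=True),
            ),
            (
                Tensor(_glorot(rng, h1, h2), requires_grad=True),
                Tensor(np.zeros(h2), requires_grad=True),
            ),
        ]
        sage = [
            Tensor(_glorot(rng, 2 * config.gat_out, h1), requires_grad=True),
            Tensor(_glorot(rng, 2 * h1, h2), requires_grad=True),
        ]
        return cls(config=config, gat_heads=heads, gcn=gcn, sage=sage)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for W, a in self.gat_heads:
            out += [W, a]
        for W, b in self.gcn:
            out += [W, b]
        out += list(self.sage)
        return out


@dataclass
class NodeEmbeddings:
    """GNN output H plus the score-time augmentation H~ = [H || H^node]."""

    ids: list[str]
    H: np.ndarray
    H_node: np.ndarray

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.ids)}

    @property
    def H_tilde(self) -> np.ndarray:
        return np.concatenate([self.H, self.H_node], axis=1)

    def tilde(self, node: str) -> np.ndarray:
        return self.H_tilde[self._index[node]]


# ---------------------------------------------------------------------------
# directed edge-index helpers
# ---------------------------------------------------------------------------

def _directed_arrays(
    edges: set[tuple[str, str]], index: dict[str, int], self_loop_isolated: bool = False,
    self_loop_all: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Both orientations of each undirected edge as (src j, dst i) arrays."""
    src, dst = [], []
    touched = set()
    for a, b in sorted(edges):
        ia, ib = index[a], index[b]
        src += [ia, ib]
        dst += [ib, ia]
        touched.update((ia, ib))
    if self_loop_all:
        for i in range(len(index)):
            src.append(i)
            dst.append(i)
    elif self_loop_isolated:
        for i in range(len(index)):
            if i not in touched:
                src.append(i)
                dst.append(i)
    return np.asarray(src, dtype=np.intp), np.asarray(dst, dtype=np.intp)


def _degrees(dst: np.ndarray, n: int) -> np.ndarray:
    deg = np.zeros(n)
    np.add.at(deg, dst, 1.0)
    return deg


# ---------------------------------------------------------------------------
# differentiable layer cores (Tensor in, Tensor out)
# ---------------------------------------------------------------------------

def _gat_core(
    X: Tensor, src: np.ndarray, dst: np.ndarray, n: int, params: GnnParams
) -> Tensor:
    outs: list[Tensor] = []
    for W, a in params.gat_heads:
        WH = X @ W
        cat = concat([gather(WH, dst), gather(WH, src)], axis=1)  # [W H_i || W H_j]
        e = (cat @ a).leaky_relu(params.config.leaky_slope).reshape(len(src))
        alpha = segment_softmax(e, dst, n).reshape(len(src), 1)
        outs.append(segment_sum(gather(WH, src) * alpha, dst, n))
    out = outs[0]
    for o in outs[1:]:
        out = out + o
    return out * (1.0 / len(outs))


def _gcn_core(
    X: Tensor, src: np.ndarray, dst: np.ndarray, n: int, W: Tensor, b: Tensor
) -> Tensor:
    deg = _degrees(dst, n)
    if len(src):
        coeff = 1.0 / np.sqrt(deg[src] * deg[dst])
        msg = gather(X, src) * Tensor(coeff[:, None])
        agg = segment_sum(msg, dst, n)
    else:
        agg = Tensor(np.zeros((n, X.shape[1])))
    return (agg @ W + b).relu()


def _sample_neighbors(
    src: np.ndarray, dst: np.ndarray, n: int, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if fraction >= 1.0:
        return src, dst
    keep_s, keep_d = [], []
    for i in range(n):
        mask = dst == i
        nbr = src[mask]
        if len(nbr) == 0:
            continue
        m = math.ceil(fraction * len(nbr))
        chosen = rng.choice(len(nbr), size=m, replace=False)
        keep_s += list(nbr[np.sort(chosen)])
        keep_d += [i] * m
    return np.asarray(keep_s, dtype=np.intp), np.asarray(keep_d, dtype=np.intp)


def _sage_core(
    X: Tensor, src: np.ndarray, dst: np.ndarray, n: int, W: Tensor
) -> Tensor:
    counts = _degrees(dst, n)
    if len(src):
        total = segment_sum(gather(X, src), dst, n)
        mean = total * Tensor((1.0 / np.maximum(counts, 1.0))[:, None])
    else:
        mean = Tensor(np.zeros((n, X.shape[1])))
    return (concat([X, mean], axis=1) @ W).relu()


# ---------------------------------------------------------------------------
# public layer operations on FeatureTables
# ---------------------------------------------------------------------------

def gat_layer(
    features: FeatureTable, edges: set[tuple[str, str]], params: GnnParams
) -> FeatureTable:
    """One attention layer over the given (undirected) edges.

    Isolated nodes attend to themselves (alpha_ii = 1) so every node gets an
    output row. Attention rows sum to one by construction of the softmax.
    """
    index = features.index()
    src, dst = _directed_arrays(edges, index, self_loop_isolated=True)
    out = _gat_core(Tensor(features.X), src, dst, len(features.ids), params)
    return FeatureTable(features.ids, out.data)


def gcn_layer(
    features: FeatureTable,
    gene_edges: set[tuple[str, str]],
    W: Tensor,
    b: Tensor,
    self_loops: bool = False,
) -> FeatureTable:
    """Symmetric-degree-normalized graph convolution with ReLU.

    The literal update has no self term; nodes with an empty neighborhood
    output ReLU(b). `self_loops` adds i to N_i (and to the degrees).
    """
    index = features.index()
    src, dst = _directed_arrays(gene_edges, index, self_loop_all=self_loops)
    out = _gcn_core(Tensor(features.X), src, dst, len(features.ids), W, b)
    return FeatureTable(features.ids, out.data)


def sage_layer(
    features: FeatureTable,
    assoc_edges: set[tuple[str, str]],
    W: Tensor,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Sampled-neighborhood mean aggregation with self-concatenation.

    Nodes with no incident edges aggregate a zero vector, so their output is
    ReLU(W [H_i || 0]).
    """
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")
    index = features.index()
    src, dst = _directed_arrays(assoc_edges, index)
    rng = np.random.default_rng(seed)
    src, dst = _sample_neighbors(src, dst, len(features.ids), sample_fraction, rng)
    out = _sage_core(Tensor(features.X), src, dst, len(features.ids), W)
    return FeatureTable(features.ids, out.data)


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def forward_tensor(
    net: HeteroModuleNetwork,
    features: FeatureTable,
    params: GnnParams,
    seed: int = 0,
) -> tuple[list[str], Tensor]:
    """Differentiable forward pass; returns (ids, H) with H an (N, out) Tensor."""
    ids = features.ids
    index = features.index()
    n = len(ids)
    cfg = params.config

    src, dst = _directed_arrays(net.hetero_edges(), index, self_loop_isolated=True)
    H1 = _gat_core(Tensor(features.X), src, dst, n, params)

    # branch A: two GCN layers on the gene-gene subgraph (gene nodes only)
    gene_ids = [i for i, node in enumerate(ids) if node in net.gene_nodes]
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    gsrc, gdst = [], []
    for a, b in sorted(net.genes.edges):
        ia, ib = gene_pos[index[a]], gene_pos[index[b]]
        gsrc += [ia, ib]
        gdst += [ib, ia]
    if cfg.gcn_self_loops:
        for j in range(len(gene_ids)):
            gsrc.append(j)
            gdst.append(j)
    gsrc = np.asarray(gsrc, dtype=np.intp)
    gdst = np.asarray(gdst, dtype=np.intp)
    Hg = gather(H1, np.asarray(gene_ids, dtype=np.intp))
    for W, b in params.gcn:
        Hg = _gcn_core(Hg, gsrc, gdst, len(gene_ids), W, b)

    # branch B: two SAGE layers on the disease-gene subgraph (all nodes)
    asrc, adst = _directed_arrays(
        {(d, g) for d, g in net.associations.pairs}, index
    )
    rng = np.random.default_rng(seed)
    Hs = H1
    for W in params.sage:
        s, d = _sample_neighbors(asrc, adst, n, cfg.sample_fraction, rng)
        Hs = _sage_core(Hs, s, d, n, W)

    # aggregate: elementwise sum; disease nodes have no GCN contribution
    H = Hs + segment_sum(Hg, np.asarray(gene_ids, dtype=np.intp), n)
    if cfg.normalize_output:
        norm = ((H * H).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        H = H / norm
    return ids, H


def forward(
    net: HeteroModuleNetwork,
    features: FeatureTable,
    params: GnnParams,
    node_vectors: dict[str, np.ndarray],
    seed: int = 0,
) -> NodeEmbeddings:
    """Full forward pass producing numpy node embeddings and H~."""
    ids, H = forward_tensor(net, features, params, seed=seed)
    H_node = np.stack([node_vectors[i] for i in ids])
    return NodeEmbeddings(ids=ids, H=H.data, H_node=H_node)
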