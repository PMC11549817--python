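"""End-to-end orchestration: augment -> embed -> candidates -> GNN -> rank.

`PipelineConfig.published()` carries the hyperparameters used at full scale
on curated disease-gene data (embedding dim 128, walk length 64, 10 walks,
in-out parameter 0.3, window 5, 10 skip-gram iterations; GAT width 128 with
2 heads; branch widths (64, 8); learning rate 0.0009, 10 epochs, 50
negatives per positive, augmentation depth l = 10).
`PipelineConfig.small()` is a proportionate profile for networks of a few
hundred nodes, used by the test-bench and the synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hetero_gnn import FeatureTable, GnnConfig, GnnParams, NodeEmbeddings, forward
from .l3_augment import augment
from .module_embedding import (
    CandidateSet,
    EmbeddingTable,
    WalkCorpus,
    generate_candidates,
    generate_walks,
    moduleize,
    train_embeddings,
)
from .network_model import (
    AssociationSet,
    GeneGraph,
    HeteroModuleNetwork,
    ModuleSet,
    build_network,
)
from .train_predict import RankingResult, TrainingConfig, rank, train


@dataclass
class PipelineConfig:
    # L3 augmentation
    l: int = 10
    # walks and skip-gram
    dim: int = 128
    window: int = 5
    walk_length: int = 64
    num_walks: int = 10
    p_return: float = 1.0
    q_inout: float = 0.3
    sg_epochs: int = 10
    sg_negative: int = 5
    # candidate generation
    k_candidates: int = 100
    # GNN
    gat_out: int = 128
    heads: int = 2
    hidden: tuple[int, int] = (64, 8)
    sample_fraction: float = 1.0
    gcn_self_loops: bool = False
    # training
    learning_rate: float = 0.0009
    gnn_epochs: int = 10
    negative_ratio: int = 50
    margin: float = 1.0

    @classmethod
    def published(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def small(cls) -> "PipelineConfig":
        """Profile proportionate to a few-hundred-node synthetic network."""
        return cls(
            dim=32,
            walk_length=20,
            gat_out=32,
            hidden=(16, 8),
            gnn_epochs=30,
            negative_ratio=10,
        )

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class PipelineResult:
    network: HeteroModuleNetwork
    added_edges: set[tuple[str, str]]
    corpus: WalkCorpus
    embeddings: EmbeddingTable
    candidates: CandidateSet
    node_embeddings: NodeEmbeddings
    ranking: RankingResult
    params: GnnParams | None = None
    losses: list[float] = field(default_factory=list)


def build_features(embeddings: EmbeddingTable, ids: list[str]) -> FeatureTable:
    """Initial GNN features H^0 = [node embedding || module embedding]."""
    X = np.stack([embeddings.feature(n) for n in ids])
    return FeatureTable(ids=ids, X=X)


def run_pipeline(
    observed: GeneGraph,
    train_assoc: AssociationSet,
    modules: ModuleSet,
    cfg: PipelineConfig,
    seed: int = 0,
    use_augment: bool = True,
    use_modules: bool = True,
) -> PipelineResult:
    """Run the full prioritization pipeline on one training split.

    `use_augment` / `use_modules` select the ablation variants: with modules
    off, the module corpus is unused and every module embedding falls back
    to the node embedding (so H^0 duplicates it, preserving dimensions).
    """
    if use_augment:
        graph, added = augment(observed, cfg.l)
    else:
        graph, added = observed.copy(), set()
    mods = modules if use_modules else ModuleSet({})
    net = build_network(graph, train_assoc, mods)

    node_walks = generate_walks(
        net,
        num_walks=cfg.num_walks,
        walk_length=cfg.walk_length,
        p_return=cfg.p_return,
        q_inout=cfg.q_inout,
        seed=seed,
    )
    assignment = mods.assignment()
    module_walks = moduleize(node_walks, mods, assignment)
    corpus = WalkCorpus(node_walks, module_walks)
    embeddings = train_embeddings(
        node_walks,
        module_walks,
        assignment,
        dim=cfg.dim,
        window=cfg.window,
        epochs=cfg.sg_epochs,
        negative=cfg.sg_negative,
        seed=seed + 1,
    )
    candidates = generate_candidates(embeddings, net, k=cfg.k_candidates)

    ids = sorted(net.all_nodes)
    features = build_features(embeddings, ids)
    tcfg = TrainingConfig(
        gnn=GnnConfig(
            in_dim=2 * cfg.dim,
            gat_out=cfg.gat_out,
            heads=cfg.heads,
            hidden=cfg.hidden,
            sample_fraction=cfg.sample_fraction,
            gcn_self_loops=cfg.gcn_self_loops,
        ),
        learning_rate=cfg.learning_rate,
        epochs=cfg.gnn_epochs,
        negative_ratio=cfg.negative_ratio,
        margin=cfg.margin,
        seed=seed + 2,
    )
    params, losses = train(net, features, embeddings.node_vectors, tcfg)
    node_emb = forward(net, features, params, embeddings.node_vectors, seed=seed + 3)
    ranking = rank(node_emb, candidates)
    return PipelineResult(
        network=net,
        added_edges=added,
        corpus=corpus,
        embeddings=embeddings,
        candidates=candidates,
        node_embeddings=node_emb,
        ranking=ranking,
        params=params,
        losses=losses,
    )
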