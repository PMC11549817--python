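"""Margin-loss training of the GNN and candidate re-ranking.

A disease-gene pair is scored by the cosine of the augmented embeddings
H~ = [H || H^node] of its endpoints, where H is the GNN output and H^node
the walk-based node embedding. Positives are the training associations;
negatives are drawn uniformly from unconnected disease-gene pairs, p per
positive, and resampled every epoch. The loss per pair is the margin hinge
max(0, 1 - y * score) with y in {+1, -1} — note a 0/1 label encoding would
make the hinge constant for negatives, so negatives are labeled -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, gather
from .hetero_gnn import (
    FeatureTable,
    GnnConfig,
    GnnParams,
    NodeEmbeddings,
    forward_tensor,
)
from .module_embedding import CandidateSet
from .network_model import HeteroModuleNetwork


@dataclass
class TrainingConfig:
    """Optimization hyperparameters; GNN shapes ride along in `gnn`."""

    gnn: GnnConfig
    learning_rate: float = 0.0009
    epochs: int = 10
    negative_ratio: int = 50
    margin: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")


@dataclass
class LabeledPairs:
    """(disease, gene, label) triples; label +1 for associations, -1 otherwise."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass
class RankingResult:
    """Per-disease candidates re-scored by the trained model, best first."""

    per_disease: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def top(self, disease: str, i: int) -> list[str]:
        return [g for g, _ in self.per_disease.get(disease, [])[:i]]


def sample_negatives(
    net: HeteroModuleNetwork,
    positives: set[tuple[str, str]],
    p: int,
    seed: int = 0,
) -> LabeledPairs:
    """Positives plus p x |positives| distinct unconnected pairs labeled -1.

    If fewer unconnected pairs exist than requested, all of them are used
    (with a warning).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    diseases = sorted(net.disease_nodes)
    genes = sorted(net.gene_nodes)
    pool = [
        (d, g) for d in diseases for g in genes if (d, g) not in net.associations.pairs
    ]
    want = p * len(positives)
    rng = np.random.default_rng(seed)
    if want > len(pool):
        warnings.warn(
            f"requested {want} negatives but only {len(pool)} unconnected pairs exist"
        )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen = [pool[i] for i in idx]
    labeled = [(d, g, 1) for d, g in sorted(positives)]
    labeled += [(d, g, -1) for d, g in chosen]
    return LabeledPairs(labeled)


def margin_loss(y_hat: float, y: int, margin: float = 1.0) -> float:
    """Hinge max(0, margin - y_hat * y); zero once the score clears the margin."""
    if y not in (1, -1):
        raise ValueError("labels must be +1 or -1")
    return max(0.0, margin - y_hat * y)


def pair_score(emb: NodeEmbeddings, d: str, g: str) -> float:
    """Cosine similarity of the augmented embeddings of d and g, in [-1, 1]."""
    hd, hg = emb.tilde(d), emb.tilde(g)
    nd, ng = np.linalg.norm(hd), np.linalg.norm(hg)
    if nd == 0 or ng == 0:
        warnings.warn("zero-norm embedding in pair_score; returning 0")
        return 0.0
    return float(hd @ hg / (nd * ng))


def _cosine_batch(Htilde: Tensor, di: np.ndarray, gi: np.ndarray) -> Tensor:
    """Differentiable cosine for index pairs over rows of Htilde."""
    A = gather(Htilde, di)
    B = gather(Htilde, gi)
    dot = (A * B).sum(axis=1, keepdims=True)
    na = ((A * A).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    nb = ((B * B).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return dot / (na * nb)


def train(
    net: HeteroModuleNetwork,
    features: FeatureTable,
    node_vectors: dict[str, np.ndarray],
    config: TrainingConfig,
) -> tuple[GnnParams, list[float]]:
    """Full-batch Adam minimization of the mean margin loss.

    Negatives are resampled each epoch (seeded); returns the trained
    parameters and the per-epoch loss log. Raises on NaN loss.
    """
    positives = set(net.associations.pairs)
    if not positives:
        raise ValueError("no positive associations to train on")
    params = GnnParams.init(config.gnn, seed=config.seed)
    opt = Adam(params.tensors(), lr=config.learning_rate)
    index = {n: i for i, n in enumerate(features.ids)}
    H_node = Tensor(np.stack([node_vectors[i] for i in features.ids]))

    losses: list[float] = []
    for epoch in range(config.epochs):
        labeled = sample_negatives(
            net, positives, config.negative_ratio, seed=config.seed + 1000 + epoch
        )
        di = np.asarray([index[d] for d, _, _ in labeled.pairs], dtype=np.intp)
        gi = np.asarray([index[g] for _, g, _ in labeled.pairs], dtype=np.intp)
        y = np.asarray([[lab] for _, _, lab in labeled.pairs], dtype=np.float64)

        opt.zero_grad()
        ids, H = forward_tensor(net, features, params, seed=config.seed + epoch)
        Htilde = concat([H, H_node], axis=1)
        scores = _cosine_batch(Htilde, di, gi)
        loss = (Tensor(np.full_like(y, config.margin)) - scores * Tensor(y)).relu().mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}: {loss.data}")
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return params, losses


def rank(emb: NodeEmbeddings, candidates: CandidateSet) -> RankingResult:
    """Re-score each disease's candidate list with the trained embeddings.

    Only candidate pairs are ever scored; sorting is score descending, gene
    id ascending at ties.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for d, cands in candidates.per_disease.items():
        scored = [(g, pair_score(emb, d, g)) for g, _ in cands]
        scored.sort(key=lambda t: (-t[1], t[0]))
        out[d] = scored
    return RankingResult(out)
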