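"""Rank-based evaluation: Top@i precision/recall/F1, association precision,
AUC, k-fold cross-validation, and the ablation harness.

Top@i metrics macro-average over the disease set D (diseases with at least
one true test gene and a non-empty prediction list):

    Prec   = mean_d |T(d) & P_i(d)| / |P_i(d)|
    Recall = mean_d |T(d) & P_i(d)| / |T(d)|
    F1     = mean_d 2 |T(d) & P_i(d)| / (|P_i(d)| + |T(d)|)

Association precision (AP) is micro-averaged over a per-disease cut
k_d = min(|T(d)|, 10):  AP = sum_d |T(d) & P_{k_d}(d)| / sum_d |P_{k_d}(d)|.
AUC is the rank-based (Mann-Whitney) statistic over scored candidate pairs
labeled by held-out truth, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .network_model import AssociationSet, GeneGraph, ModuleSet
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .train_predict import RankingResult

AblationVariant = Literal["GNN", "GNN*", "GNN-M", "GNN*-M"]

#: ablation variant -> (use_augment, use_modules); GNN*-M is the full method
ABLATIONS: dict[str, tuple[bool, bool]] = {
    "GNN": (False, False),
    "GNN-M": (False, True),
    "GNN*": (True, False),
    "GNN*-M": (True, True),
}


@dataclass
class EvalReport:
    """Metrics of one evaluated ranking (optionally one CV fold)."""

    topk: dict[int, dict[str, float]] = field(default_factory=dict)
    ap: float = float("nan")
    auc: float = float("nan")
    n_diseases: int = 0


@dataclass
class CvReport:
    """Per-fold reports plus their means."""

    folds: list[EvalReport]
    external_folds: list[EvalReport] = field(default_factory=list)

    @staticmethod
    def _mean(reports: list[EvalReport], attr: str) -> float:
        vals = [getattr(r, attr) for r in reports if np.isfinite(getattr(r, attr))]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_ap(self) -> float:
        return self._mean(self.folds, "ap")

    def mean_auc(self) -> float:
        return self._mean(self.folds, "auc")


def _eligible(ranking: RankingResult, truth: AssociationSet) -> dict[str, set[str]]:
    by_d = truth.by_disease()
    return {
        d: t for d, t in by_d.items()
        if t and ranking.per_disease.get(d)
    }


def topk_metrics(
    ranking: RankingResult, truth: AssociationSet, i: int
) -> tuple[float, float, float]:
    """Macro-averaged (precision, recall, F1) at cut i.

    A disease's precision denominator is the actual |P_i(d)|, which may be
    below i when fewer candidates exist.
    """
    if i < 1:
        raise ValueError("i must be >= 1")
    eligible = _eligible(ranking, truth)
    if not eligible:
        raise ValueError("no disease has both truth genes and predictions")
    prec = rec = f1 = 0.0
    for d, t in eligible.items():
        top = ranking.top(d, i)
        hits = len(t & set(top))
        prec += hits / len(top)
        rec += hits / len(t)
        f1 += 2 * hits / (len(top) + len(t))
    n = len(eligible)
    return prec / n, rec / n, f1 / n


def association_precision(ranking: RankingResult, truth: AssociationSet) -> float:
    """Micro-averaged precision at the per-disease cut k_d = min(|T(d)|, 10)."""
    eligible = _eligible(ranking, truth)
    if not eligible:
        raise ValueError("no disease has both truth genes and predictions")
    num = den = 0
    for d, t in eligible.items():
        k_d = min(len(t), 10)
        top = ranking.top(d, k_d)
        num += len(t & set(top))
        den += min(len(top), 10)
    return num / den


def auc(scored_pairs: list[tuple[float, int]]) -> float:
    """Rank-based AUC over (score, binary label) pairs; ties count 1/2."""
    labels = [lab for _, lab in scored_pairs]
    if len(set(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    scores = [s for s, _ in scored_pairs]
    return float(roc_auc_score(labels, scores))


def ranking_auc(ranking: RankingResult, truth: AssociationSet) -> float:
    """AUC over all scored candidate pairs, labeled by held-out truth."""
    by_d = truth.by_disease()
    pairs = [
        (score, int(g in by_d.get(d, set())))
        for d, cands in ranking.per_disease.items()
        for g, score in cands
    ]
    return auc(pairs)


def evaluate_ranking(ranking: RankingResult, truth: AssociationSet) -> EvalReport:
    """Top@{3,10}, AP and AUC of one ranking against held-out truth."""
    report = EvalReport(n_diseases=len(_eligible(ranking, truth)))
    for i in (3, 10):
        p, r, f = topk_metrics(ranking, truth, i)
        report.topk[i] = {"precision": p, "recall": r, "f1": f}
    report.ap = association_precision(ranking, truth)
    try:
        report.auc = ranking_auc(ranking, truth)
    except ValueError:
        report.auc = float("nan")
    return report


def kfold_split(
    pairs: set[tuple[str, str]], n_folds: int = 10, seed: int = 0
) -> list[list[tuple[str, str]]]:
    """Seeded association-level partition into folds of near-equal size."""
    ordered = sorted(pairs)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [[ordered[i] for i in test] for _, test in kf.split(ordered)]


def tenfold_cv(
    observed: GeneGraph,
    associations: AssociationSet,
    modules: ModuleSet,
    cfg: PipelineConfig,
    seed: int = 0,
    n_folds: int = 10,
    external: AssociationSet | None = None,
    use_augment: bool = True,
    use_modules: bool = True,
) -> CvReport:
    """Association-level k-fold cross-validation of the full pipeline.

    Each fold's network is rebuilt from the training associations only; the
    held-out fold is the internal truth. When an external association set is
    given it is evaluated against the same per-fold predictions.
    """
    folds = kfold_split(associations.pairs, n_folds=n_folds, seed=seed)
    fold_reports: list[EvalReport] = []
    external_reports: list[EvalReport] = []
    for f, test_pairs in enumerate(folds):
        test = AssociationSet(set(test_pairs))
        train = AssociationSet(associations.pairs - test.pairs)
        result = run_pipeline(
            observed, train, modules, cfg, seed=seed + 100 * f,
            use_augment=use_augment, use_modules=use_modules,
        )
        fold_reports.append(evaluate_ranking(result.ranking, test))
        if external is not None:
            external_reports.append(evaluate_ranking(result.ranking, external))
    return CvReport(folds=fold_reports, external_folds=external_reports)


def run_ablation(
    variant: str,
    observed: GeneGraph,
    train_assoc: AssociationSet,
    modules: ModuleSet,
    heldout: AssociationSet,
    cfg: PipelineConfig,
    seed: int = 0,
) -> tuple[EvalReport, PipelineResult]:
    """Run one ablation variant on a fixed train/heldout split.

    GNN = neither augmentation nor modules; GNN-M = modules only;
    GNN* = augmentation only; GNN*-M = the complete method.
    """
    if variant not in ABLATIONS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    use_augment, use_modules = ABLATIONS[variant]
    result = run_pipeline(
        observed, train_assoc, modules, cfg, seed=seed,
        use_augment=use_augment, use_modules=use_modules,
    )
    return evaluate_ranking(result.ranking, heldout), result
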