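"""L3-principle link prediction and graph augmentation for the gene graph.

Two proteins joined by many paths of length three are likely to interact
directly (unlike triadic closure, which counts length-2 paths and is a poor
model of the complementary-interface geometry of protein binding). For a
node pair (x, y) the raw count is

    CN(x, y) = sum_{u,v} a_xu a_uv a_vy

over intermediate nodes u, v, with a the binary adjacency indicator. The RA
(resource allocation) and AA (Adamic-Adar) variants penalize high-degree
intermediates with per-path weights (1/k_u + 1/k_v) and
(1/log k_u + 1/log k_v) respectively.

Augmentation: for every source node x, the top `l` candidates under each of
the three scores are selected (S_CN, S_RA, S_AA) and x is connected to each
node of the union S_CN | S_RA | S_AA. Scores are computed once on the
original graph; a single pass, no iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .network_model import GeneGraph

Variant = Literal["CN", "RA", "AA"]
VARIANTS: tuple[Variant, ...] = ("CN", "RA", "AA")


@dataclass
class L3ScoreSet:
    """Per-source candidate scores for one L3 variant.

    Candidates never include the source or its current neighbors; all scores
    are strictly positive (zero-evidence pairs are simply absent).
    """

    source: str
    variant: Variant
    scores: dict[str, float]


def _aa_weight(k: int, log_base: float | None) -> float:
    # Degree-1 intermediates cannot sit on an L3 path interior (they need a
    # neighbor on each side), so k <= 1 never occurs for a contributing term;
    # guard defensively since log(1) = 0 would divide by zero.
    if k <= 1:
        return 0.0
    return 1.0 / math.log(k) if log_base is None else 1.0 / math.log(k, log_base)


def _pair_weight(variant: Variant, ku: int, kv: int, log_base: float | None) -> float:
    if variant == "CN":
        return 1.0
    if variant == "RA":
        return 1.0 / ku + 1.0 / kv
    if variant == "AA":
        return _aa_weight(ku, log_base) + _aa_weight(kv, log_base)
    raise ValueError(f"unknown L3 variant {variant!r}")


def l3_score(
    graph: GeneGraph,
    x: str,
    y: str,
    variant: Variant,
    log_base: float | None = None,
) -> float:
    """L3 score of the unordered pair (x, y); symmetric in its arguments.

    `log_base` applies to the AA variant only; ``None`` means natural log,
    the convention of the Adamic-Adar literature.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown L3 variant {variant!r}")
    if x not in graph.nodes or y not in graph.nodes:
        missing = x if x not in graph.nodes else y
        raise KeyError(f"node {missing!r} not in graph")
    if x == y:
        raise ValueError("L3 score is defined for distinct nodes only")
    adj = graph.neighbors()
    deg = {n: len(ns) for n, ns in adj.items()}
    total = 0.0
    for u in adj[x]:
        for v in adj[u] & adj[y]:
            total += _pair_weight(variant, deg[u], deg[v], log_base)
    return total


def _score_from_source(
    adj: dict[str, set[str]],
    deg: dict[str, int],
    x: str,
    variant: Variant,
    log_base: float | None,
) -> dict[str, float]:
    """All positive L3 scores from x via sparse two-hop frontier expansion.

    Walks x -> u -> v -> y accumulating the per-(u, v) weight onto y; y is
    restricted to non-neighbors of x (and not x itself).
    """
    excluded = adj[x] | {x}
    scores: dict[str, float] = {}
    for u in adj[x]:
        for v in adj[u]:
            w = _pair_weight(variant, deg[u], deg[v], log_base)
            if w == 0.0:
                continue
            for y in adj[v]:
                if y not in excluded:
                    scores[y] = scores.get(y, 0.0) + w
    return scores


def score_set(
    graph: GeneGraph, x: str, variant: Variant, log_base: float | None = None
) -> L3ScoreSet:
    """All positive-score candidates for source x under one variant."""
    if x not in graph.nodes:
        raise KeyError(f"node {x!r} not in graph")
    adj = graph.neighbors()
    deg = {n: len(ns) for n, ns in adj.items()}
    return L3ScoreSet(x, variant, _score_from_source(adj, deg, x, variant, log_base))


def _top_l(scores: dict[str, float], l: int) -> list[str]:
    # score descending, then lexicographic id: deterministic at rank ties.
    # Scores are compared after rounding to 9 decimals so that ties are
    # robust to floating-point summation order.
    ranked = sorted(scores.items(), key=lambda kv: (-round(kv[1], 9), kv[0]))
    return [node for node, s in ranked[:l] if s > 0]


def top_l_candidates(
    graph: GeneGraph,
    x: str,
    variant: Variant,
    l: int,
    log_base: float | None = None,
) -> list[str]:
    """Top-l candidates for x: score descending, id ascending at ties.

    Zero-score candidates are never returned, even when fewer than l nodes
    score positively — an edge on zero path evidence has no support.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    return _top_l(score_set(graph, x, variant, log_base).scores, l)


def augment(
    graph: GeneGraph, l: int, log_base: float | None = None
) -> tuple[GeneGraph, set[tuple[str, str]]]:
    """Single-pass top-l union augmentation.

    For every node x, edges x-s are added for s in S_CN(x) | S_RA(x) | S_AA(x),
    each S_* holding x's top-l candidates under that variant. All scores are
    computed on the input graph. Returns the augmented graph and the set of
    newly added (sorted) edges.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    adj = graph.neighbors()
    deg = {n: len(ns) for n, ns in adj.items()}
    added: set[tuple[str, str]] = set()
    for x in sorted(graph.nodes):
        union: set[str] = set()
        for variant in VARIANTS:
            scores = _score_from_source(adj, deg, x, variant, log_base)
            union.update(_top_l(scores, l))
        for s in union:
            edge = (x, s) if x <= s else (s, x)
            if edge not in graph.edges:
                added.add(edge)
    out = graph.copy()
    for a, b in added:
        out.add_edge(a, b)
    return out, added
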