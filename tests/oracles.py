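"""Independent reference implementations used only as test oracles.

Everything here is deliberately written in a different style from the
package: dense matrices and exhaustive enumeration instead of sparse
frontier expansion and segment operations.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# L3 scoring: dense tensor-contraction over all ordered (u, v) pairs
# ---------------------------------------------------------------------------

def l3_score_matrix(A: np.ndarray, variant: str, log_base: float | None = None) -> np.ndarray:
    """All-pairs L3 scores sum_{u,v} a_xu a_uv a_vy w(k_u, k_v) as a dense matrix."""
    n = A.shape[0]
    deg = A.sum(axis=1)

    def f(k: float) -> float:
        if variant == "CN":
            return 1.0
        if variant == "RA":
            return 1.0 / k if k > 0 else 0.0
        if variant == "AA":
            if k <= 1:
                return 0.0
            return 1.0 / math.log(k) if log_base is None else 1.0 / math.log(k, log_base)
        raise ValueError(variant)

    w = np.array([f(k) for k in deg])
    # weight matrix W[u, v] = a_uv * (f(k_u) + f(k_v))
    W = A * (w[:, None] + w[None, :]) if variant != "CN" else A.copy()
    S = A @ W @ A
    np.fill_diagonal(S, 0.0)
    return S


def augment_brute(A: np.ndarray, names: list[str], l: int) -> set[tuple[str, str]]:
    """Brute-force top-l union augmentation; returns the set of added edges."""
    n = A.shape[0]
    added: set[tuple[str, str]] = set()
    mats = {v: l3_score_matrix(A, v) for v in ("CN", "RA", "AA")}
    for x in range(n):
        union: set[int] = set()
        for v in ("CN", "RA", "AA"):
            cands = [
                (-round(mats[v][x, y], 9), names[y], y)
                for y in range(n)
                if y != x and A[x, y] == 0 and mats[v][x, y] > 0
            ]
            cands.sort()
            union.update(y for _, _, y in cands[:l])
        for y in union:
            a, b = sorted((names[x], names[y]))
            if A[x, y] == 0:
                added.add((a, b))
    return added


# ---------------------------------------------------------------------------
# GNN layers: dense per-node recomputation
# ---------------------------------------------------------------------------

def gat_dense(
    X: np.ndarray,
    adj: dict[int, set[int]],
    heads: list[tuple[np.ndarray, np.ndarray]],
    slope: float = 0.2,
) -> np.ndarray:
    """Dense attention layer; isolated nodes attend to themselves."""
    n = X.shape[0]
    outs = []
    for W, a in heads:
        WH = X @ W
        out = np.zeros_like(WH)
        for i in range(n):
            nbrs = sorted(adj.get(i, set())) or [i]
            e = []
            for j in nbrs:
                z = np.concatenate([WH[i], WH[j]]) @ a.ravel()
                e.append(z if z > 0 else slope * z)
            e = np.asarray(e)
            alpha = np.exp(e - e.max())
            alpha /= alpha.sum()
            out[i] = sum(al * WH[j] for al, j in zip(alpha, nbrs))
        outs.append(out)
    return np.mean(outs, axis=0)


def gcn_dense(X: np.ndarray, A: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ReLU(D^-1/2 A D^-1/2 X W + b), zero rows for isolated nodes' sums."""
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    norm = dinv[:, None] * A * dinv[None, :]
    return np.maximum(norm @ X @ W + b, 0.0)


def sage_dense(
    X: np.ndarray, neighbor_sets: dict[int, list[int]], W: np.ndarray
) -> np.ndarray:
    """ReLU(W-concat form): per node, [H_i || mean of given neighbors] @ W."""
    n = X.shape[0]
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        nbrs = neighbor_sets.get(i, [])
        mean = np.mean([X[j] for j in nbrs], axis=0) if nbrs else np.zeros(X.shape[1])
        out[i] = np.maximum(np.concatenate([X[i], mean]) @ W, 0.0)
    return out


# ---------------------------------------------------------------------------
# AUC: exhaustive pair counting
# ---------------------------------------------------------------------------

def auc_pair_counting(scored: list[tuple[float, int]]) -> float:
    pos = [s for s, y in scored if y == 1]
    neg = [s for s, y in scored if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
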