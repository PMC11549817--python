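"""Skip-gram with negative sampling (SGNS) for walk corpora.

A compact word2vec-style trainer: tokens within a symmetric window of each
center token are positive contexts; negatives are drawn from the unigram
distribution raised to the 3/4 power. Updates are plain SGD with a linearly
decaying learning rate, applied in vectorized minibatches. Deterministic for
a fixed seed (single-threaded by construction). Frequent-word subsampling is
omitted: walk corpora over networks of a few thousand nodes have no
stopword-like extreme frequencies.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    sentences: list[list[str]],
    dim: int = 128,
    window: int = 5,
    epochs: int = 10,
    negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 0.0001,
    seed: int = 0,
    batch_size: int = 256,
) -> dict[str, np.ndarray]:
    """Train SGNS on token sequences; returns token -> input embedding."""
    if not sentences or all(len(s) == 0 for s in sentences):
        raise ValueError("corpus is empty")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for sent in sentences:
        for tok in sent:
            i = vocab.setdefault(tok, len(vocab))
            if i == len(counts):
                counts.append(0)
            counts[i] += 1
    n_vocab = len(vocab)
    rng = np.random.default_rng(seed)

    # noise distribution: unigram^0.75
    noise = np.asarray(counts, dtype=np.float64) ** 0.75
    noise /= noise.sum()

    # (center, context) pairs from the fixed symmetric window
    centers_l, contexts_l = [], []
    for sent in sentences:
        ids = [vocab[t] for t in sent]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_l.append(c)
                    contexts_l.append(ids[j])
    centers = np.asarray(centers_l, dtype=np.intp)
    contexts = np.asarray(contexts_l, dtype=np.intp)
    n_pairs = len(centers)
    if n_pairs == 0:
        # all sentences are singletons; embeddings stay at initialization
        W = (rng.random((n_vocab, dim)) - 0.5) / dim
        return {tok: W[i].copy() for tok, i in vocab.items()}

    W = (rng.random((n_vocab, dim)) - 0.5) / dim  # input (center) vectors
    C = np.zeros((n_vocab, dim))                  # output (context) vectors

    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo:lo + batch_size]
            cur_lr = max(min_lr, lr * (1 - step / total_steps))
            step += 1
            c_idx = centers[sel]
            o_idx = contexts[sel]
            n_idx = rng.choice(n_vocab, size=(len(sel), negative), p=noise)

            vc = W[c_idx]                       # (B, d)
            uo = C[o_idx]                       # (B, d)
            un = C[n_idx]                       # (B, k, d)

            g_pos = _sigmoid((vc * uo).sum(axis=1)) - 1.0            # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, un))        # (B, k)

            grad_vc = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
            grad_uo = g_pos[:, None] * vc
            grad_un = g_neg[:, :, None] * vc[:, None, :]

            # accumulate and normalize by occurrence count: frequent (hub)
            # tokens recur many times within a batch, and summed stale
            # gradients would grow multiplicatively and diverge
            n_flat = n_idx.ravel()
            gW = np.zeros_like(W)
            np.add.at(gW, c_idx, grad_vc)
            cW = np.maximum(np.bincount(c_idx, minlength=n_vocab), 1)
            W -= cur_lr * gW / cW[:, None]
            gC = np.zeros_like(C)
            np.add.at(gC, o_idx, grad_uo)
            np.add.at(gC, n_flat, grad_un.reshape(-1, dim))
            cC = np.maximum(
                np.bincount(o_idx, minlength=n_vocab)
                + np.bincount(n_flat, minlength=n_vocab), 1)
            C -= cur_lr * gC / cC[:, None]

    return {tok: W[i].copy() for tok, i in vocab.items()}
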