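"""Brute-force reference implementations used to pin the vectorized code.

Everything here is written as plainly as possible (explicit loops, set
arithmetic) and independently of the package's numpy formulations.
"""

from __future__ import annotations

import math

import numpy as np


def jaccard_oracle(rows: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard via explicit index sets."""
    n = rows.shape[0]
    supports = [set(np.flatnonzero(r).tolist()) for r in rows]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = supports[i] | supports[j]
            out[i, j] = len(supports[i] & supports[j]) / len(union) if union else 0.0
    return out


def cosine_oracle(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ni = math.sqrt(sum(v * v for v in x[i]))
            nj = math.sqrt(sum(v * v for v in x[j]))
            if ni == 0.0 or nj == 0.0:
                continue
            out[i, j] = sum(a * b for a, b in zip(x[i], x[j])) / (ni * nj)
    return out


def normalize_oracle(a: np.ndarray) -> np.ndarray:
    """Per-entry (A + I)_{ij} / sqrt(d_i d_j) with self-loop degrees."""
    n = a.shape[0]
    a_hat = a + np.eye(n)
    deg = a_hat.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = a_hat[i, j] / math.sqrt(deg[i] * deg[j])
    return out


def gcn_oracle(
    norm_adj: np.ndarray, x: np.ndarray, weights: list[np.ndarray], activation: str = "relu"
) -> list[np.ndarray]:
    """Per-node message passing: sum normalized neighbor+self features, then
    multiply by W, then activate."""
    acts = {"relu": lambda v: np.maximum(v, 0.0), "identity": lambda v: v}
    act = acts[activation]
    n = x.shape[0]
    z = x
    outputs = []
    for w in weights:
        agg = np.zeros_like(z)
        for i in range(n):
            for j in range(n):
                agg[i] += norm_adj[i, j] * z[j]
        z = act(np.array([agg[i] @ w for i in range(n)]))
        outputs.append(z)
    return outputs


def scale_weighted_oracle(layers: list[np.ndarray], factors: np.ndarray) -> np.ndarray:
    """E[i, offset_l + c] = factors[i, l] * Z^l[i, c]."""
    n = layers[0].shape[0]
    total = sum(z.shape[1] for z in layers)
    out = np.zeros((n, total))
    offset = 0
    for l, z in enumerate(layers):
        for i in range(n):
            for c in range(z.shape[1]):
                out[i, offset + c] = factors[i, l] * z[i, c]
        offset += z.shape[1]
    return out


def binary_loss_oracle(y: np.ndarray, p: np.ndarray, eps: float = 1e-7) -> float:
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, eps), 1.0 - eps)
        total += -(yi * math.log(pi) + (1.0 - yi) * math.log(1.0 - pi))
    return total


def multiclass_loss_oracle(y_onehot: np.ndarray, p: np.ndarray, eps: float = 1e-7) -> float:
    total = 0.0
    for row_y, row_p in zip(y_onehot, p):
        for yc, pc in zip(row_y, row_p):
            total += -yc * math.log(min(max(pc, eps), 1.0 - eps))
    return total


def macro_f1_oracle(y_true: np.ndarray, y_pred: np.ndarray, labels) -> float:
    """Per-class harmonic-mean F1, averaged over the given labels."""
    f1s = []
    for c in labels:
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * precision * recall / (precision + recall) if precision + recall else 0.0)
    return float(np.mean(f1s))


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    return a + a.T
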