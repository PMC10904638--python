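"""Construction of the two graph views: DDI topology and feature-KNN.

The model consumes two graphs over the same drug node set:

* the *topology view* ``G_adj``, whose edges are the known drug-drug
  interactions (restricted to training pairs so held-out labels never leak
  into message passing), and
* the *feature view* ``G_knn``, which connects each drug to its top-K most
  feature-similar drugs (cosine similarity of node feature rows), adding
  plausible-but-unobserved links the topology view is missing.

Both adjacencies are renormalized as D^{-1/2} (A + I) D^{-1/2} with
self-loops before GCN message passing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .featurization import FeatureMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionDataset",
    "GraphView",
    "build_topology_graph",
    "cosine_similarity",
    "build_knn_graph",
    "normalize_adjacency",
]


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Unordered pair stored with the lower index first."""
    return (i, j) if i < j else (j, i)


@dataclass
class InteractionDataset:
    """Drug pair interactions, optionally labeled with an event type.

    Pairs are unordered, canonicalized ``i < j``, unique and free of
    self-pairs.  ``labels`` is ``None`` for a label-free (all-positive)
    binary dataset, otherwise an integer event type in ``[0, n_types)``.
    """

    drug_ids: list[str]
    pairs: np.ndarray  # [m, 2] int, i < j
    labels: np.ndarray | None = None  # [m] int
    n_types: int | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        n = len(self.drug_ids)
        if self.pairs.size:
            if self.pairs.min() < 0 or self.pairs.max() >= n:
                raise ValueError("pair index out of range")
            if (self.pairs[:, 0] == self.pairs[:, 1]).any():
                raise ValueError("self-pairs are not allowed")
            if (self.pairs[:, 0] > self.pairs[:, 1]).any():
                raise ValueError("pairs must be canonicalized with i < j")
            uniq = {tuple(p) for p in self.pairs}
            if len(uniq) != len(self.pairs):
                raise ValueError("duplicate pairs are not allowed")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.pairs),):
                raise ValueError("labels must align with pairs")
            if self.n_types is None:
                self.n_types = int(self.labels.max()) + 1 if self.labels.size else 0
            if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_types):
                raise ValueError("labels must lie in [0, n_types)")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in self.pairs}


@dataclass
class GraphView:
    """A binary adjacency plus its symmetric GCN normalization."""

    name: str  # "topology" | "feature"
    adjacency: np.ndarray  # [n, n] symmetric, zero diagonal
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        if self.normalized is None:
            self.normalized = normalize_adjacency(self.adjacency)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


def build_topology_graph(
    data: InteractionDataset,
    excluded_pairs: Iterable[tuple[int, int]] = (),
) -> GraphView:
    """Adjacency of the DDI network: A[i, j] = 1 iff (i, j) is a known DDI.

    ``excluded_pairs`` (e.g. the held-out test pairs of a CV fold) are left
    out of the adjacency so their labels cannot leak into message passing.
    """
    n = data.n_drugs
    excluded = {canonical_pair(*p) for p in excluded_pairs}
    a = np.zeros((n, n), dtype=np.float64)
    for i, j in data.pairs:
        if i >= n or j >= n:
            raise ValueError(f"pair ({i}, {j}) out of range for {n} drugs")
        if (int(i), int(j)) in excluded:
            continue
        a[i, j] = a[j, i] = 1.0
    return GraphView(name="topology", adjacency=a)


def cosine_similarity(features: FeatureMatrix | np.ndarray) -> SimilarityMatrix:
    """Pairwise cosine similarity of node feature rows.

    Zero-norm rows get similarity 0 against everything (including
    themselves): an attribute-free drug carries no evidence of similarity.
    """
    if isinstance(features, FeatureMatrix):
        drug_ids = list(features.drug_ids)
        x = features.values
    else:
        x = np.asarray(features, dtype=np.float64)
        drug_ids = [str(i) for i in range(x.shape[0])]
    if not np.isfinite(x).all():
        raise ValueError("feature matrix contains non-finite entries")
    sim = _sk_cosine(x)  # leaves zero-norm rows at similarity 0
    sim = np.clip(0.5 * (sim + sim.T), -1.0, 1.0)
    return SimilarityMatrix(drug_ids=drug_ids, values=sim, kind="cosine")


def build_knn_graph(similarity: SimilarityMatrix | np.ndarray, k: int) -> GraphView:
    """Feature graph: each node linked to its top-``k`` most similar nodes.

    Selection is per-node (self excluded) with ties at rank ``k`` broken by
    the lowest node index; the undirected edge set is the union over both
    directions.  ``k >= n`` is clamped to ``n - 1`` with a warning.
    """
    s = similarity.values if isinstance(similarity, SimilarityMatrix) else np.asarray(similarity)
    n = s.shape[0]
    if s.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        logger.warning("k=%d >= n=%d; clamping to %d", k, n, n - 1)
        k = n - 1
    a = np.zeros((n, n), dtype=np.float64)
    order_keys = np.arange(n)
    for i in range(n):
        row = s[i].copy()
        row[i] = -np.inf  # self excluded
        # sort by similarity desc, then node index asc (deterministic ties)
        ranked = np.lexsort((order_keys, -row))
        for j in ranked[:k]:
            a[i, j] = a[j, i] = 1.0  # union symmetrization
    return GraphView(name="feature", adjacency=a)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Renormalized adjacency D^{-1/2} (A + I) D^{-1/2}.

    ``D`` is the degree matrix of ``A + I`` (self-loops included), so every
    node — isolated ones included — has degree >= 1 and the result has a
    strictly positive diagonal.
    """
    a = np.asarray(adjacency, dtype=np.float64)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diagonal(a).any():
        raise ValueError("adjacency must have a zero diagonal")
    a_hat = a + np.eye(n)
    inv_sqrt_deg = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return inv_sqrt_deg[:, None] * a_hat * inv_sqrt_deg[None, :]
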