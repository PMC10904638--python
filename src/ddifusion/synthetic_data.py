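"""Seed-reproducible synthetic DDI datasets with planted cluster structure.

The generator encodes the modeling assumption the predictor relies on —
drug pairs that interact tend to have similar features — as a planted
latent-cluster model:

* each of ``n_clusters`` clusters owns a random binary descriptor prototype
  per feature type; a drug copies its cluster's prototypes with independent
  per-bit flip probability ``flip_noise``;
* the probability that a pair interacts is logistic in the Jaccard
  similarity of their cluster prototypes with slope ``signal`` (gamma); the
  intercept is solved numerically so the expected edge count matches
  ``density`` x C(n, 2).  ``signal = 0`` severs the feature-interaction
  link entirely, giving an unlearnable null dataset;
* the event type of an interaction is a deterministic function of the
  (unordered) cluster pair, with cluster pairs packed onto the ``n_types``
  labels so expected label counts stay balanced.

Every draw flows from one ``numpy`` generator seeded by the config, so the
same config yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .featurization import DescriptorMatrix
from .graph_views import InteractionDataset

__all__ = ["SynthConfig", "SyntheticDataset", "generate"]

_FEATURE_TYPE_NAMES = ("substructure", "enzyme", "target")


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's reference study
    conditions for desk-scale experiments."""

    n_drugs: int = 200
    n_clusters: int = 5
    n_descriptors: int = 50  # per feature type
    n_feature_types: int = 3
    flip_noise: float = 0.05  # beta: per-bit prototype flip probability
    density: float = 0.1  # expected edge fraction of C(n, 2)
    n_types: int = 5  # R event types
    signal: float = 12.0  # gamma: similarity -> interaction slope
    prototype_density: float = 0.3  # P(bit set) in a cluster prototype
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_clusters, self.n_descriptors, self.n_feature_types, self.n_types) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise must lie in [0, 1]")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        n_cluster_pairs = self.n_clusters * (self.n_clusters + 1) // 2
        if self.n_types > n_cluster_pairs:
            raise ValueError(
                f"n_types={self.n_types} exceeds the {n_cluster_pairs} distinct cluster pairs"
            )


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth that produced it."""

    config: SynthConfig
    descriptors: dict[str, DescriptorMatrix]
    interactions: InteractionDataset
    cluster_labels: np.ndarray  # [n_drugs] true cluster of each drug
    pair_probabilities: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _feature_type_names(n: int) -> list[str]:
    names = list(_FEATURE_TYPE_NAMES[:n])
    names += [f"feature{t}" for t in range(len(names), n)]
    return names


def _prototype_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.logical_and(a, b).sum())
    union = float(np.logical_or(a, b).sum())
    return inter / union if union else 0.0


def _balanced_type_map(
    cluster_pairs: list[tuple[int, int]], expected_edges: np.ndarray, n_types: int
) -> dict[tuple[int, int], int]:
    """Assign cluster pairs to event types, largest expected edge mass first,
    each to the currently lightest type (deterministic greedy balancing)."""
    order = sorted(range(len(cluster_pairs)), key=lambda i: (-expected_edges[i], cluster_pairs[i]))
    load = np.zeros(n_types)
    mapping: dict[tuple[int, int], int] = {}
    for i in order:
        t = int(np.argmin(load))  # ties -> lowest type id
        mapping[cluster_pairs[i]] = t
        load[t] += expected_edges[i]
    return mapping


def generate(cfg: SynthConfig) -> SyntheticDataset:
    """Draw one synthetic dataset under ``cfg`` (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    n, n_clusters = cfg.n_drugs, cfg.n_clusters
    clusters = np.arange(n) % n_clusters  # equal-sized clusters
    type_names = _feature_type_names(cfg.n_feature_types)

    prototypes = {
        name: rng.random((n_clusters, cfg.n_descriptors)) < cfg.prototype_density
        for name in type_names
    }
    drug_ids = [f"D{i:04d}" for i in range(n)]
    descriptors: dict[str, DescriptorMatrix] = {}
    for name in type_names:
        bits = prototypes[name][clusters]
        flips = rng.random((n, cfg.n_descriptors)) < cfg.flip_noise
        values = np.logical_xor(bits, flips).astype(np.int8)
        descriptors[name] = DescriptorMatrix(
            drug_ids=list(drug_ids),
            feature_type=name,
            descriptor_ids=[f"{name}_{d:04d}" for d in range(cfg.n_descriptors)],
            values=values,
        )

    # cluster-level prototype similarity (mean Jaccard across feature types)
    sim = np.zeros((n_clusters, n_clusters))
    for a in range(n_clusters):
        for b in range(a, n_clusters):
            s = float(
                np.mean(
                    [_prototype_jaccard(prototypes[t][a], prototypes[t][b]) for t in type_names]
                )
            )
            sim[a, b] = sim[b, a] = s

    ii, jj = np.triu_indices(n, k=1)
    pair_sim = sim[clusters[ii], clusters[jj]]

    def mean_prob(intercept: float) -> float:
        return float(expit(intercept + cfg.signal * pair_sim).mean())

    span = cfg.signal * float(pair_sim.max(initial=0.0)) + 50.0
    intercept = brentq(lambda c: mean_prob(c) - cfg.density, -span, span, xtol=1e-10)
    probs = expit(intercept + cfg.signal * pair_sim)
    edge_mask = rng.random(len(probs)) < probs

    cluster_pairs = [(a, b) for a in range(n_clusters) for b in range(a, n_clusters)]
    expected = np.array(
        [
            probs[(np.minimum(clusters[ii], clusters[jj]) == a) & (np.maximum(clusters[ii], clusters[jj]) == b)].sum()
            for a, b in cluster_pairs
        ]
    )
    type_map = _balanced_type_map(cluster_pairs, expected, cfg.n_types)

    pairs = np.column_stack([ii[edge_mask], jj[edge_mask]])
    pair_clusters = np.sort(
        np.column_stack([clusters[pairs[:, 0]], clusters[pairs[:, 1]]]), axis=1
    )
    labels = np.array([type_map[(int(a), int(b))] for a, b in pair_clusters], dtype=np.int64)

    interactions = InteractionDataset(
        drug_ids=list(drug_ids), pairs=pairs, labels=labels, n_types=cfg.n_types
    )
    return SyntheticDataset(
        config=cfg,
        descriptors=descriptors,
        interactions=interactions,
        cluster_labels=clusters,
        pair_probabilities=probs,
    )
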