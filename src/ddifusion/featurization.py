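"""Drug featurization: descriptor encoding, Jaccard similarity, block splicing.

A drug is described by the set of descriptors it is associated with per
feature type (e.g. chemical substructures, enzymes, targets).  The raw 0/1
descriptor vectors are high-dimensional and sparse, so the node features fed
to the graph encoders are instead the rows of the drug-by-drug Jaccard
similarity matrix of each feature type, horizontally spliced across types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DescriptorMatrix",
    "SimilarityMatrix",
    "FeatureMatrix",
    "DEFAULT_BLOCK_ORDER",
    "encode_descriptors",
    "jaccard_similarity",
    "build_feature_matrix",
    "features_from_descriptors",
]

#: fixed splicing order for the standard feature types; types not listed
#: here follow in lexicographic order.  A single-type dataset (e.g. only
#: chemical substructures) takes the same code path with one block.
DEFAULT_BLOCK_ORDER = ("substructure", "enzyme", "target")


@dataclass
class DescriptorMatrix:
    """Binary drug x descriptor association matrix for one feature type."""

    drug_ids: list[str]
    feature_type: str
    descriptor_ids: list[str]
    values: np.ndarray  # [n_drugs, n_descriptors], entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValueError("duplicate drug ids in DescriptorMatrix")
        if self.values.shape != (len(self.drug_ids), len(self.descriptor_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.descriptor_ids)} descriptors"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("DescriptorMatrix entries must be exactly 0 or 1")


@dataclass
class SimilarityMatrix:
    """Symmetric drug x drug similarity in [0, 1]."""

    drug_ids: list[str]
    values: np.ndarray  # [n, n]
    kind: str  # "jaccard" | "cosine"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.drug_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over drug_ids")
        if not self.name:
            self.name = self.kind


@dataclass
class FeatureMatrix:
    """Node attribute matrix X: similarity blocks spliced column-wise."""

    drug_ids: list[str]
    values: np.ndarray  # [n, F]
    block_spans: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def encode_descriptors(
    associations: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
    vocabulary: Sequence[str],
    feature_type: str = "feature",
) -> DescriptorMatrix:
    """One-hot encode drug -> descriptor-set associations.

    ``associations`` maps each drug id to the descriptor ids it is associated
    with (a dict, or a sequence of ``(drug_id, descriptor_ids)`` pairs; the
    latter form is validated against duplicate drug ids).  Entry ``(i, k)``
    of the result is 1 iff drug ``i`` carries descriptor ``k`` of
    ``vocabulary``; unknown descriptor ids are rejected.
    """
    items = list(associations.items()) if isinstance(associations, Mapping) else list(associations)
    drug_ids = [d for d, _ in items]
    if len(drug_ids) != len(set(drug_ids)):
        dupes = sorted({d for d in drug_ids if drug_ids.count(d) > 1})
        raise ValueError(f"duplicate drug id(s): {', '.join(dupes)}")
    vocab_index = {v: k for k, v in enumerate(vocabulary)}
    if len(vocab_index) != len(vocabulary):
        raise ValueError("vocabulary contains duplicate descriptor ids")
    values = np.zeros((len(items), len(vocabulary)), dtype=np.int8)
    for i, (drug, descriptors) in enumerate(items):
        for desc in descriptors:
            k = vocab_index.get(desc)
            if k is None:
                raise ValueError(f"drug {drug!r}: unknown descriptor id {desc!r}")
            values[i, k] = 1
    return DescriptorMatrix(
        drug_ids=list(drug_ids),
        feature_type=feature_type,
        descriptor_ids=list(vocabulary),
        values=values,
    )


def jaccard_similarity(descriptors: DescriptorMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarity |d_i n d_j| / |d_i u d_j| over binary rows.

    A pair where both rows are all-zero has an empty union; its similarity is
    defined as 0 ("no evidence of similarity").
    """
    values = np.asarray(descriptors.values, dtype=np.float64)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("jaccard_similarity requires a binary matrix")
    intersection = values @ values.T
    sizes = values.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - intersection
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, intersection / np.where(union > 0, union, 1.0), 0.0)
    sim = 0.5 * (sim + sim.T)  # exact symmetry against fp round-off
    return SimilarityMatrix(
        drug_ids=list(descriptors.drug_ids),
        values=sim,
        kind="jaccard",
        name=descriptors.feature_type,
    )


def build_feature_matrix(blocks: Sequence[SimilarityMatrix]) -> FeatureMatrix:
    """Splice similarity blocks into the node feature matrix X.

    Blocks are concatenated horizontally in the given order; every block must
    carry the identical drug ordering.  Column spans per block are recorded
    so individual blocks remain recoverable.
    """
    if len(blocks) == 0:
        raise ValueError("at least one similarity block is required")
    drug_ids = list(blocks[0].drug_ids)
    for b in blocks[1:]:
        if list(b.drug_ids) != drug_ids:
            raise ValueError("all blocks must share an identical drug_ids ordering")
    spans: list[tuple[str, int, int]] = []
    offset = 0
    for b in blocks:
        width = b.values.shape[1]
        spans.append((b.name, offset, offset + width))
        offset += width
    values = np.concatenate([b.values for b in blocks], axis=1)
    return FeatureMatrix(drug_ids=drug_ids, values=values, block_spans=spans)


def features_from_descriptors(
    descriptors: Mapping[str, DescriptorMatrix],
    order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Standard featurization pipeline: per-type Jaccard similarity blocks
    spliced in a fixed order (default order, then remaining types sorted)."""
    if order is None:
        order = [t for t in DEFAULT_BLOCK_ORDER if t in descriptors]
        order += sorted(set(descriptors) - set(order))
    missing = [t for t in order if t not in descriptors]
    if missing:
        raise ValueError(f"unknown feature type(s): {', '.join(missing)}")
    return build_feature_matrix([jaccard_similarity(descriptors[t]) for t in order])
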