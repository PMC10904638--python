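"""Multi-scale GCN encoding and dual-view attention fusion.

Each graph view is encoded by an L-layer GCN,

    Z^l = sigma( A~ Z^{l-1} W^l ),   Z^0 = X,

and *all* per-layer outputs (the multi-scale stack Z^1..Z^L) are kept:
shallow layers carry local, high-dimensional detail; deep layers carry
higher-order, lower-dimensional semantics.  Per view, the spliced stack
Z^1 || ... || Z^L feeds one linear map that produces a per-node attention
logit for every scale; the logits pass through LeakyReLU, a softmax across
scales, and a row-wise l2 normalization.  The resulting factor a^l scales
every column of the node's Z^l block before the blocks are re-spliced into
the view embedding E_y.  The two view embeddings are fused by elementwise
summation into the final drug embedding E_drug = E_adj + E_knn.

Public functions accept and return numpy arrays; the training loop reuses
the underlying tensor graph (see ``_t``-suffixed internals) so inference
and gradient paths share one implementation of the math.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurization import FeatureMatrix
from .graph_views import GraphView

__all__ = [
    "GcnParams",
    "AttentionParams",
    "ScaleStack",
    "AttentionFactors",
    "DrugEmbedding",
    "glorot_uniform",
    "gcn_forward",
    "splice_scales",
    "attention_factors",
    "scale_weighted_embedding",
    "fuse_views",
]

_ACTIVATIONS = {
    "relu": ad.relu,
    "leaky_relu": ad.leaky_relu,
    "identity": lambda t: ad.as_tensor(t),
}

#: layer widths used at public-benchmark scale; a configured depth L <= 5 takes
#: the first L entries.
DEFAULT_LAYER_DIMS = (256, 128, 64, 32, 16)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Fan-based uniform initialization in +-sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class GcnParams:
    """Per-view GCN weights W^1..W^L and the activation name.

    The two views share architecture (layer dims) but never parameters.
    """

    weights: list[np.ndarray]
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("at least one GCN layer is required")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        for l, (wa, wb) in enumerate(zip(self.weights, self.weights[1:]), start=1):
            if np.asarray(wa).shape[1] != np.asarray(wb).shape[0]:
                raise ValueError(f"layer {l} output dim does not feed layer {l + 1}")
        for w in self.weights:
            if not np.isfinite(np.asarray(w)).all():
                raise ValueError("GCN weights must be finite")

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return tuple(np.asarray(w).shape[1] for w in self.weights)

    @classmethod
    def initialize(
        cls,
        rng: np.random.Generator,
        n_features: int,
        layer_dims: Sequence[int],
        activation: str = "relu",
    ) -> "GcnParams":
        dims = [n_features, *layer_dims]
        weights = [glorot_uniform(rng, a, b) for a, b in zip(dims, dims[1:])]
        return cls(weights=weights, activation=activation)


@dataclass
class AttentionParams:
    """One linear map per view: spliced stack (sum of dims) -> L logits."""

    weight: np.ndarray  # [sum(d_l), L]
    bias: np.ndarray  # [L]
    negative_slope: float = 0.2

    @classmethod
    def initialize(
        cls, rng: np.random.Generator, total_dim: int, n_scales: int
    ) -> "AttentionParams":
        return cls(
            weight=glorot_uniform(rng, total_dim, n_scales),
            bias=np.zeros(n_scales),
        )


@dataclass
class ScaleStack:
    """Per-layer GCN outputs Z^1..Z^L for one view."""

    view: str
    layers: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a ScaleStack needs at least one layer output")

    @property
    def n_scales(self) -> int:
        return len(self.layers)

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return tuple(z.shape[1] for z in self.layers)

    @property
    def total_dim(self) -> int:
        return int(sum(self.layer_dims))

    def column_offsets(self) -> list[tuple[int, int]]:
        """Column span of each scale block inside the spliced matrix."""
        edges = np.concatenate([[0], np.cumsum(self.layer_dims)])
        return list(zip(edges[:-1].tolist(), edges[1:].tolist()))


@dataclass
class AttentionFactors:
    """Per-node, per-scale attention weights for one view.

    ``softmax_factors`` are the factors right after the softmax (rows sum to
    1); ``factors`` are the final weights after the additional row-wise l2
    normalization (rows have unit Euclidean norm).  Both are strictly
    positive.
    """

    view: str
    factors: np.ndarray  # [n, L], post-l2
    softmax_factors: np.ndarray  # [n, L], pre-l2

    @property
    def n_scales(self) -> int:
        return self.factors.shape[1]


@dataclass
class DrugEmbedding:
    """Fused drug embedding with per-view provenance kept for ablations."""

    values: np.ndarray  # [n, sum(d_l)]
    e_adj: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    e_knn: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# tensor-graph internals (shared by inference and training)
# ---------------------------------------------------------------------------


def gcn_layers_t(
    norm_adj: np.ndarray, x, weights: Sequence, activation: str = "relu"
) -> list[Tensor]:
    act = _ACTIVATIONS[activation]
    adj_t = ad.as_tensor(norm_adj)
    z = ad.as_tensor(x)
    outputs: list[Tensor] = []
    for w in weights:
        z = act(ad.matmul(ad.matmul(adj_t, z), ad.as_tensor(w)))
        outputs.append(z)
    return outputs


def splice_t(layers: Sequence) -> Tensor:
    return ad.concat_cols(list(layers))


def attention_t(spliced, weight, bias, negative_slope: float = 0.2) -> tuple[Tensor, Tensor]:
    """Returns (softmax factors, l2-normalized factors) as tensors."""
    logits = ad.leaky_relu(
        ad.add(ad.matmul(ad.as_tensor(spliced), ad.as_tensor(weight)), ad.as_tensor(bias)),
        negative_slope=negative_slope,
    )
    soft = ad.softmax_rows(logits)
    return soft, ad.l2_normalize_rows(soft)


def scale_weighted_t(layers: Sequence, factors) -> Tensor:
    factors = ad.as_tensor(factors)
    weighted = []
    for l, z in enumerate(layers):
        a_l = ad.slice_cols(factors, l, l + 1)  # [n, 1] broadcasts over block
        weighted.append(ad.mul(ad.as_tensor(z), a_l))
    return ad.concat_cols(weighted)


# ---------------------------------------------------------------------------
# public numpy-facing operations
# ---------------------------------------------------------------------------


def gcn_forward(view: GraphView, features: FeatureMatrix | np.ndarray, params: GcnParams) -> ScaleStack:
    """Run the L-layer GCN on one view and keep every per-layer output."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if view.normalized.shape[0] != x.shape[0]:
        raise ValueError("feature row count does not match the graph node count")
    if x.shape[1] != np.asarray(params.weights[0]).shape[0]:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match W^1 input dim "
            f"{np.asarray(params.weights[0]).shape[0]}"
        )
    layers = gcn_layers_t(view.normalized, x, params.weights, params.activation)
    return ScaleStack(view=view.name, layers=[t.value for t in layers])


def splice_scales(stack: ScaleStack) -> np.ndarray:
    """Row-wise concatenation Z^1 || ... || Z^L."""
    return splice_t(stack.layers).value


def attention_factors(spliced: np.ndarray, params: AttentionParams, view: str = "") -> AttentionFactors:
    """Per-node scale weights: LeakyReLU(linear) -> softmax -> row-wise l2."""
    soft, final = attention_t(spliced, params.weight, params.bias, params.negative_slope)
    return AttentionFactors(view=view, factors=final.value, softmax_factors=soft.value)


def scale_weighted_embedding(stack: ScaleStack, att: AttentionFactors) -> np.ndarray:
    """E_y = (a^1 . Z^1) || ... || (a^L . Z^L): factor (i, l) scales every
    column of node i's scale-l block."""
    if att.factors.shape != (stack.layers[0].shape[0], stack.n_scales):
        raise ValueError("attention factors do not match the scale stack")
    return scale_weighted_t(stack.layers, att.factors).value


def fuse_views(e_adj: np.ndarray, e_knn: np.ndarray) -> DrugEmbedding:
    """Fuse the two view embeddings by elementwise summation."""
    e_adj = np.asarray(e_adj, dtype=np.float64)
    e_knn = np.asarray(e_knn, dtype=np.float64)
    if e_adj.shape != e_knn.shape:
        raise ValueError(f"view embedding shapes differ: {e_adj.shape} vs {e_knn.shape}")
    return DrugEmbedding(values=e_adj + e_knn, e_adj=e_adj, e_knn=e_knn)
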