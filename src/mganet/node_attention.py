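"""Spatial branch: masked multi-head graph attention over the channel graph.

Each electrode (node) aggregates its graph neighbours' features, weighted by
learned attention coefficients.  For a centre node c with neighbourhood
N(c), a head with shared weight matrix W and attention vector a computes

    u_ck   = LeakyReLU( aT [W f_c || W f_k] ),   slope 0.2,
    alpha_ck = softmax over k in N(c) of u_ck   (masked: non-neighbours
                                                 get exactly zero weight),
    out_c  = logistic( (1/L) sum_l sum_k alpha_ck^(l) W^(l) f_k ),

averaging over the L heads.  Layers are stacked with a dense ReLU map
between graph-attention layers.  A separate spatial-domain attention
produces a row-stochastic node-by-node matrix that re-mixes node feature
columns.

These functions are plain-numpy, single-sample reference semantics; the
trainable batched model in :mod:`mganet.model` mirrors them and is tested
for agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel_graph import ChannelGraph, neighbors
from .exceptions import NumericError, ParameterError, ValidationError

__all__ = [
    "GatHeadParams",
    "GatLayerParams",
    "SpatialAttentionParams",
    "AttentionMatrix",
    "attention_coefficients",
    "gat_layer",
    "stack_gat",
    "spatial_attention",
    "apply_spatial_attention",
    "init_gat_layer",
    "init_spatial_attention",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0.0, x, slope * x)


@dataclass(frozen=True)
class GatHeadParams:
    """One attention head: shared weight map and attention vector.

    ``W`` maps node features F_in -> F_out; ``a_vec`` (length 2*F_out)
    scores the concatenated centre/neighbour projections; ``leaky_slope``
    is the negative slope of the score activation (0.2 by default).
    """

    W: np.ndarray = field(repr=False)
    a_vec: np.ndarray = field(repr=False)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        a = np.asarray(self.a_vec, dtype=float).ravel()
        if a.shape[0] != 2 * W.shape[1]:
            raise ParameterError(
                f"a_vec length {a.shape[0]} != 2 * F_out ({2 * W.shape[1]})"
            )
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(a))):
            raise ValidationError("head parameters must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "a_vec", a)

    @property
    def f_in(self) -> int:
        return self.W.shape[0]

    @property
    def f_out(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class GatLayerParams:
    """A multi-head layer: L heads with matching shapes, averaged outputs."""

    heads: tuple[GatHeadParams, ...]

    def __post_init__(self) -> None:
        heads = tuple(self.heads)
        if not heads:
            raise ParameterError("a layer needs at least one head")
        f_in, f_out = heads[0].f_in, heads[0].f_out
        for h in heads[1:]:
            if (h.f_in, h.f_out) != (f_in, f_out):
                raise ParameterError("all heads must share F_in and F_out")
        object.__setattr__(self, "heads", heads)

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @property
    def f_in(self) -> int:
        return self.heads[0].f_in

    @property
    def f_out(self) -> int:
        return self.heads[0].f_out


@dataclass(frozen=True)
class SpatialAttentionParams:
    """Parameters of the spatial-domain attention bilinear form.

    With X the (n, F) node-feature matrix (a time block is averaged over
    its time axis first), the raw score matrix is

        A_S = P_s * logistic( (X Q1) Q2 (Q3 X^T) + Q_s )      (elementwise *)

    with shapes Q1: (F, 1), Q2: (1, T), Q3: (T, F), P_s and Q_s: (n, n),
    so the product collapses the feature axis and yields an n-by-n score
    matrix whatever the inner width T.  Rows are then softmax-normalized.
    """

    P_s: np.ndarray = field(repr=False)
    Q_s: np.ndarray = field(repr=False)
    Q1: np.ndarray = field(repr=False)
    Q2: np.ndarray = field(repr=False)
    Q3: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("P_s", "Q_s", "Q1", "Q2", "Q3"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class AttentionMatrix:
    """A row-stochastic attention matrix with an optional binary mask.

    Rows sum to 1 within 1e-6; entries where ``mask == 0`` are exactly 0.
    """

    values: np.ndarray = field(repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("attention matrix must be 2D")
        if np.any(vals < 0):
            raise ValidationError("attention entries must be nonnegative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("attention rows must sum to 1")
        if self.mask is not None:
            mask = np.asarray(self.mask)
            if mask.shape != vals.shape:
                raise ValidationError("mask shape must match values")
            if np.any(vals[mask == 0] != 0.0):
                raise ValidationError("masked entries must be exactly zero")
            object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def attention_coefficients(
    head: GatHeadParams,
    features: np.ndarray,
    graph: ChannelGraph,
    center: int,
) -> np.ndarray:
    """Masked attention weights of one centre node over its neighbourhood.

    Returns weights aligned with ``neighbors(graph, center)`` (ascending
    index order); they are positive and sum to 1.
    """
    features = np.asarray(features, dtype=float)
    nbrs = neighbors(graph, center)
    if not nbrs:
        raise ValidationError(f"node {center} is isolated")
    z = features @ head.W  # (n, F_out)
    a_src = head.a_vec[: head.f_out]
    a_dst = head.a_vec[head.f_out :]
    scores = z[center] @ a_src + z[nbrs] @ a_dst
    scores = _leaky_relu(scores, head.leaky_slope)
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def gat_layer(
    params: GatLayerParams, features: np.ndarray, graph: ChannelGraph
) -> np.ndarray:
    """One multi-head graph-attention layer.

    Output row c is the logistic of the head-averaged, attention-weighted
    sum of projected neighbour features; entries lie in (0, 1).
    """
    features = np.asarray(features, dtype=float)
    n = graph.n_nodes
    if features.shape[0] != n:
        raise ParameterError(
            f"features has {features.shape[0]} rows, graph has {n} nodes"
        )
    if features.shape[1] != params.f_in:
        raise ParameterError(
            f"features dim {features.shape[1]} != layer F_in {params.f_in}"
        )
    acc = np.zeros((n, params.f_out))
    for head in params.heads:
        z = features @ head.W
        for c in range(n):
            nbrs = neighbors(graph, c)
            alpha = attention_coefficients(head, features, graph, c)
            acc[c] += alpha @ z[nbrs]
    return _logistic(acc / params.n_heads)


def stack_gat(
    layer_params: list[GatLayerParams],
    features: np.ndarray,
    graph: ChannelGraph,
    interlayer_weights: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Stacked graph-attention layers with dense ReLU maps between them.

    Between consecutive attention layers the node features pass through
    ``ReLU(x W)`` with a shared learnable matrix per gap (identity when
    ``interlayer_weights`` is None).  The final layer's logistic output is
    returned without an interlayer ReLU.
    """
    if not layer_params:
        raise ParameterError("need at least one layer")
    if interlayer_weights is not None and len(interlayer_weights) != len(layer_params) - 1:
        raise ParameterError(
            f"need {len(layer_params) - 1} interlayer weight matrices, "
            f"got {len(interlayer_weights)}"
        )
    x = np.asarray(features, dtype=float)
    for i, layer in enumerate(layer_params):
        x = gat_layer(layer, x, graph)
        if i < len(layer_params) - 1:
            if interlayer_weights is not None:
                w = np.asarray(interlayer_weights[i], dtype=float)
                if w.shape[0] != x.shape[1]:
                    raise ParameterError(
                        f"interlayer weight {i} expects dim {w.shape[0]}, "
                        f"features have dim {x.shape[1]}"
                    )
                x = x @ w
            x = np.maximum(x, 0.0)
    return x


def spatial_attention(
    params: SpatialAttentionParams, features: np.ndarray
) -> AttentionMatrix:
    """Row-stochastic node-by-node spatial attention matrix.

    ``features`` is either an (n, F) matrix or an (n, F, T) block; a block
    is averaged over its trailing time axis before entering the bilinear
    form (the time width survives as the inner dimension of Q2/Q3).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 3:
        x = x.mean(axis=2)
    if x.ndim != 2:
        raise ParameterError(f"features must be (n, F) or (n, F, T), got {x.shape}")
    raw = params.P_s * _logistic((x @ params.Q1) @ params.Q2 @ (params.Q3 @ x.T) + params.Q_s)
    if not np.all(np.isfinite(raw)):
        raise NumericError("non-finite spatial attention scores")
    shifted = raw - raw.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return AttentionMatrix(values=e / e.sum(axis=1, keepdims=True))


def apply_spatial_attention(features: np.ndarray, attn: AttentionMatrix) -> np.ndarray:
    """Re-mix node feature columns: ``(F, n) @ A_S'`` -> (F, n).

    Because the attention matrix is row-stochastic, each output column is a
    convex combination of input node columns.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != attn.n:
        raise ParameterError(
            f"features must have {attn.n} columns, got shape {features.shape}"
        )
    return features @ attn.values


# -- initialisation ---------------------------------------------------------

def init_gat_layer(
    rng: np.random.Generator, f_in: int, f_out: int, n_heads: int
) -> GatLayerParams:
    """Glorot-scaled random initialisation of a multi-head layer."""
    scale = np.sqrt(2.0 / (f_in + f_out))
    heads = tuple(
        GatHeadParams(
            W=rng.normal(0.0, scale, size=(f_in, f_out)),
            a_vec=rng.normal(0.0, scale, size=2 * f_out),
        )
        for _ in range(n_heads)
    )
    return GatLayerParams(heads=heads)


def init_spatial_attention(
    rng: np.random.Generator, n: int, f: int, t: int
) -> SpatialAttentionParams:
    """Random initialisation of the spatial-domain attention parameters."""
    return SpatialAttentionParams(
        P_s=np.ones((n, n)),
        Q_s=np.zeros((n, n)),
        Q1=rng.normal(0.0, 1.0 / np.sqrt(f), size=(f, 1)),
        Q2=rng.normal(0.0, 1.0 / np.sqrt(t), size=(1, t)),
        Q3=rng.normal(0.0, 1.0 / np.sqrt(f), size=(t, f)),
    )
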