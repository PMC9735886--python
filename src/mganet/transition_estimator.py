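"""Transitional-stage estimator (TSE): stage-level attention over class
probabilities.

Epochs near stage boundaries blend the spectral signatures of adjacent
stages and are the main source of scoring confusion (N1 especially).  The
TSE addresses this at the *stage* level rather than the node level: after
the fused spatial/temporal features are pooled and mapped to a stage
probability vector P, a second small map produces a per-stage sigmoid
attention vector A in (0,1)^5, and the refined score is the Hadamard
product f* = A * P.  f* is intentionally left unnormalized; it is
renormalized only where a probability is required (training loss, exported
hypnogram probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericError, ParameterError, ValidationError
from .stages import N_STAGES, STAGES

__all__ = [
    "TseParams",
    "StageDistribution",
    "fuse_features",
    "global_average_pool",
    "stage_probabilities",
    "refine_with_attention",
    "classify",
    "init_tse",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TseParams:
    """Decision layer (pooled features -> 5 logits) and attention layer
    (5 probabilities -> 5 attention logits)."""

    fc1_weights: np.ndarray = field(repr=False)
    fc1_bias: np.ndarray = field(repr=False)
    fc2_weights: np.ndarray = field(repr=False)
    fc2_bias: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w1 = np.atleast_2d(np.asarray(self.fc1_weights, dtype=float))
        b1 = np.asarray(self.fc1_bias, dtype=float).ravel()
        w2 = np.atleast_2d(np.asarray(self.fc2_weights, dtype=float))
        b2 = np.asarray(self.fc2_bias, dtype=float).ravel()
        if w1.shape[0] != N_STAGES or b1.shape != (N_STAGES,):
            raise ParameterError("fc1 must map features to 5 stage logits")
        if w2.shape != (N_STAGES, N_STAGES) or b2.shape != (N_STAGES,):
            raise ParameterError("fc2 must be a 5x5 map with a 5-vector bias")
        for arr, name in ((w1, "fc1_weights"), (b1, "fc1_bias"),
                          (w2, "fc2_weights"), (b2, "fc2_bias")):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite")
        object.__setattr__(self, "fc1_weights", w1)
        object.__setattr__(self, "fc1_bias", b1)
        object.__setattr__(self, "fc2_weights", w2)
        object.__setattr__(self, "fc2_bias", b2)

    @property
    def feature_dim(self) -> int:
        return self.fc1_weights.shape[1]


@dataclass(frozen=True)
class StageDistribution:
    """Per-epoch stage scores: probabilities P, attention A, refined A*P."""

    probs: np.ndarray = field(repr=False)
    attention: np.ndarray = field(repr=False)
    refined: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).ravel()
        a = np.asarray(self.attention, dtype=float).ravel()
        r = np.asarray(self.refined, dtype=float).ravel()
        if p.shape != (N_STAGES,) or a.shape != (N_STAGES,) or r.shape != (N_STAGES,):
            raise ValidationError("probs, attention and refined must be 5-vectors")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValidationError("probs must be a probability vector")
        if np.any(a <= 0) or np.any(a >= 1):
            raise ValidationError("attention entries must lie in (0, 1)")
        if not np.allclose(r, a * p, atol=1e-12):
            raise ValidationError("refined must equal attention * probs")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "attention", a)
        object.__setattr__(self, "refined", r)


def fuse_features(spatial: np.ndarray, temporal: np.ndarray) -> np.ndarray:
    """Concatenate the two branch outputs into one feature vector.

    Trailing axes are flattened; the result has dimension
    ``spatial.size + temporal.size`` and slicing at ``spatial.size``
    recovers the two blocks.
    """
    s = np.asarray(spatial, dtype=float).ravel()
    t = np.asarray(temporal, dtype=float).ravel()
    return np.concatenate([s, t])


def global_average_pool(block: np.ndarray, axis: int = -1) -> np.ndarray:
    """Average a feature block over its structural axis (channels or time)."""
    return np.asarray(block, dtype=float).mean(axis=axis)


def stage_probabilities(params: TseParams, fused: np.ndarray) -> np.ndarray:
    """Stage probability vector P = softmax(fc1(pool(fused))).

    ``fused`` may be a 1D pooled feature vector, or a 2D
    (features x structure) block which is average-pooled over its trailing
    structural axis first.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.ndim == 2:
        fused = global_average_pool(fused, axis=-1)
    if fused.ndim != 1 or fused.shape[0] != params.feature_dim:
        raise ParameterError(
            f"fused features have dim {fused.shape}, fc1 expects "
            f"{params.feature_dim}"
        )
    logits = params.fc1_weights @ fused + params.fc1_bias
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def refine_with_attention(
    params: TseParams, probs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-level attention A = logistic(fc2(P)) and refined scores A * P.

    Because the logistic is strictly below 1, every refined entry is
    strictly smaller than the corresponding probability.
    """
    p = np.asarray(probs, dtype=float).ravel()
    if p.shape != (N_STAGES,):
        raise ParameterError(f"probs must be a 5-vector, got shape {p.shape}")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError("probs must be a valid distribution")
    attention = _logistic(params.fc2_weights @ p + params.fc2_bias)
    return attention, attention * p


def classify(refined: np.ndarray) -> str:
    """Map refined scores to a stage name by argmax.

    Ties break toward the lower class index (W < N1 < N2 < N3 < REM).
    """
    r = np.asarray(refined, dtype=float).ravel()
    if not np.all(np.isfinite(r)):
        raise NumericError("refined scores must be finite")
    return STAGES[int(np.argmax(r))]


def init_tse(rng: np.random.Generator, feature_dim: int) -> TseParams:
    """Glorot-scaled initialisation of both fully connected maps."""
    s1 = np.sqrt(2.0 / (feature_dim + N_STAGES))
    s2 = np.sqrt(2.0 / (2 * N_STAGES))
    return TseParams(
        fc1_weights=rng.normal(0, s1, (N_STAGES, feature_dim)),
        fc1_bias=np.zeros(N_STAGES),
        fc2_weights=rng.normal(0, s2, (N_STAGES, N_STAGES)),
        fc2_bias=np.zeros(N_STAGES),
    )
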