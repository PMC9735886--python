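"""Temporal branch: GRU over the epoch sequence plus temporal attention.

The gated recurrent unit follows the update convention used by this model
family:

    u_t = logistic(W_u x_t + U_u h_{t-1} + b_u)        (update gate)
    d_t = logistic(W_d x_t + U_d h_{t-1} + b_d)        (reset gate)
    hhat_t = tanh(W_h x_t + U_h (d_t * h_{t-1}) + b_h) (candidate)
    h_t = u_t * h_{t-1} + (1 - u_t) * hhat_t

Note the mixing rule: the update gate u multiplies the PREVIOUS hidden
state (many GRU write-ups attach u to the candidate instead; the two
parameterisations are equivalent up to the sign of the gate pre-activation,
but the convention here is fixed and tested).  Each new hidden coordinate
is therefore a convex combination of the previous state and the candidate.

Temporal-domain attention mirrors the spatial one: a bilinear form over
hidden states yields a T-by-T row-stochastic matrix that re-mixes hidden
state columns across time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericError, ParameterError, ValidationError
from .node_attention import AttentionMatrix

__all__ = [
    "GruParams",
    "TemporalAttentionParams",
    "HiddenStateSequence",
    "gru_cell",
    "gru_sequence",
    "temporal_attention",
    "apply_temporal_attention",
    "init_gru",
    "init_temporal_attention",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GruParams:
    """GRU weights: input maps W_*, recurrent maps U_*, biases b_*."""

    W_u: np.ndarray = field(repr=False)
    W_d: np.ndarray = field(repr=False)
    W_h: np.ndarray = field(repr=False)
    U_u: np.ndarray = field(repr=False)
    U_d: np.ndarray = field(repr=False)
    U_h: np.ndarray = field(repr=False)
    b_u: np.ndarray = field(repr=False)
    b_d: np.ndarray = field(repr=False)
    b_h: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("W_u", "W_d", "W_h", "U_u", "U_d", "U_h"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite")
            object.__setattr__(self, name, arr)
        for name in ("b_u", "b_d", "b_h"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite")
            object.__setattr__(self, name, arr)
        h = self.W_u.shape[0]
        d = self.W_u.shape[1]
        shapes = {
            "W_d": (h, d), "W_h": (h, d),
            "U_u": (h, h), "U_d": (h, h), "U_h": (h, h),
            "b_u": (h,), "b_d": (h,), "b_h": (h,),
        }
        for name, want in shapes.items():
            got = getattr(self, name).shape
            if got != want:
                raise ParameterError(f"{name} has shape {got}, expected {want}")

    @property
    def hidden_size(self) -> int:
        return self.W_u.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_u.shape[1]


@dataclass(frozen=True)
class TemporalAttentionParams:
    """Parameters of the temporal-domain attention bilinear form.

    With S the (T, H) hidden-state matrix, the raw scores are

        A_T = P_v * logistic( (S P1) P2 (P3 S^T) + Q_v )     (elementwise *)

    with P1: (H, 1), P2: (1, m), P3: (m, H), P_v and Q_v: (T, T); the
    product collapses the hidden axis to a T-by-T score matrix for any
    inner width m.  Rows are then softmax-normalized.
    """

    P_v: np.ndarray = field(repr=False)
    Q_v: np.ndarray = field(repr=False)
    P1: np.ndarray = field(repr=False)
    P2: np.ndarray = field(repr=False)
    P3: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("P_v", "Q_v", "P1", "P2", "P3"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class HiddenStateSequence:
    """Hidden states of a GRU run: row t is h_t, shape (T, H)."""

    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if not np.all(np.isfinite(states)):
            raise ValidationError("hidden states must be finite")
        object.__setattr__(self, "states", states)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.states.shape[1]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def gru_cell(params: GruParams, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU update step (see module docstring for the exact rule)."""
    x_t = np.asarray(x_t, dtype=float).ravel()
    h_prev = np.asarray(h_prev, dtype=float).ravel()
    if x_t.shape[0] != params.input_size:
        raise ParameterError(
            f"input dim {x_t.shape[0]} != expected {params.input_size}"
        )
    if h_prev.shape[0] != params.hidden_size:
        raise ParameterError(
            f"hidden dim {h_prev.shape[0]} != expected {params.hidden_size}"
        )
    u = _logistic(params.W_u @ x_t + params.U_u @ h_prev + params.b_u)
    d = _logistic(params.W_d @ x_t + params.U_d @ h_prev + params.b_d)
    hhat = np.tanh(params.W_h @ x_t + params.U_h @ (d * h_prev) + params.b_h)
    return u * h_prev + (1.0 - u) * hhat


def gru_sequence(
    params: GruParams, inputs: np.ndarray, h0: np.ndarray | None = None
) -> HiddenStateSequence:
    """Run the GRU over a (T, D) input sequence; h0 defaults to zeros."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[0] < 1:
        raise ValidationError("input sequence must have at least one step")
    h = (
        np.zeros(params.hidden_size)
        if h0 is None
        else np.asarray(h0, dtype=float).ravel()
    )
    states = np.empty((inputs.shape[0], params.hidden_size))
    for t in range(inputs.shape[0]):
        h = gru_cell(params, inputs[t], h)
        states[t] = h
    return HiddenStateSequence(states=states)


def temporal_attention(
    params: TemporalAttentionParams, states: np.ndarray | HiddenStateSequence
) -> AttentionMatrix:
    """Row-stochastic T-by-T attention over the hidden-state sequence."""
    if isinstance(states, HiddenStateSequence):
        states = states.states
    s = np.atleast_2d(np.asarray(states, dtype=float))
    raw = params.P_v * _logistic((s @ params.P1) @ params.P2 @ (params.P3 @ s.T) + params.Q_v)
    if not np.all(np.isfinite(raw)):
        raise NumericError("non-finite temporal attention scores")
    shifted = raw - raw.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return AttentionMatrix(values=e / e.sum(axis=1, keepdims=True))


def apply_temporal_attention(states: np.ndarray, attn: AttentionMatrix) -> np.ndarray:
    """Re-mix hidden-state columns across time: ``(H, T) @ A_T'`` -> (H, T)."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[1] != attn.n:
        raise ParameterError(
            f"states must have {attn.n} columns, got shape {states.shape}"
        )
    return states @ attn.values


# -- initialisation ---------------------------------------------------------

def init_gru(rng: np.random.Generator, input_size: int, hidden_size: int) -> GruParams:
    """Glorot-scaled random initialisation; biases start at zero."""
    sw = np.sqrt(2.0 / (input_size + hidden_size))
    su = np.sqrt(1.0 / hidden_size)
    return GruParams(
        W_u=rng.normal(0, sw, (hidden_size, input_size)),
        W_d=rng.normal(0, sw, (hidden_size, input_size)),
        W_h=rng.normal(0, sw, (hidden_size, input_size)),
        U_u=rng.normal(0, su, (hidden_size, hidden_size)),
        U_d=rng.normal(0, su, (hidden_size, hidden_size)),
        U_h=rng.normal(0, su, (hidden_size, hidden_size)),
        b_u=np.zeros(hidden_size),
        b_d=np.zeros(hidden_size),
        b_h=np.zeros(hidden_size),
    )


def init_temporal_attention(
    rng: np.random.Generator, t: int, h: int, m: int
) -> TemporalAttentionParams:
    """Random initialisation of the temporal-domain attention parameters."""
    return TemporalAttentionParams(
        P_v=np.ones((t, t)),
        Q_v=np.zeros((t, t)),
        P1=rng.normal(0, 1.0 / np.sqrt(h), (h, 1)),
        P2=rng.normal(0, 1.0 / np.sqrt(m), (1, m)),
        P3=rng.normal(0, 1.0 / np.sqrt(h), (m, h)),
    )
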