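"""Synthetic polysomnography generator.

Produces labeled multichannel recordings with the two statistical features
the classifier depends on, without requiring any clinical download:

* **Hypnogram dynamics** — a first-order Markov chain over the five AASM
  stages.  The default transition matrix is ``0.88 I + 0.12 (1 pi^T)``
  where ``pi = (W 0.12, N1 0.075, N2 0.45, N3 0.13, REM 0.225)``: every
  stage is sticky (self-transition >= 0.889, mimicking stage persistence)
  and the chain's exact stationary distribution is ``pi``, which places N1
  in the 5-10% occupancy range and REM in the 20-25% range typical of a
  night of sleep.
* **Stage-specific spectra** — each epoch's signal is a sum of band-limited
  sinusoids (random frequency within each band, random phase) whose RMS
  amplitudes depend on the stage, plus white noise and per-channel gain
  jitter.  W is alpha-dominant, N1 theta, N2 sigma (spindle band), N3
  delta, REM a theta+beta mix; N1 and REM share a theta emphasis so the
  transitional confusion the estimator targets is present in the data.

Waveform morphology (K-complexes, discrete spindles, artifacts) is not
emulated; realism is spectral-statistical only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import ValidationError
from .features import DEFAULT_BANDS, band_log_power
from .stages import N_STAGES

__all__ = [
    "SimulationConfig",
    "LabeledRecording",
    "DEFAULT_TRANSITION_MATRIX",
    "DEFAULT_BAND_AMPLITUDES",
    "stationary_distribution",
    "simulate_hypnogram",
    "synthesize_epoch_signal",
    "generate_dataset",
]

_TARGET_OCCUPANCY = np.array([0.12, 0.075, 0.45, 0.13, 0.225])
_STICKINESS = 0.88

# Sticky chain with exact stationary distribution _TARGET_OCCUPANCY.
DEFAULT_TRANSITION_MATRIX: np.ndarray = (
    _STICKINESS * np.eye(N_STAGES)
    + (1.0 - _STICKINESS) * np.tile(_TARGET_OCCUPANCY, (N_STAGES, 1))
)
DEFAULT_TRANSITION_MATRIX.setflags(write=False)

# Stage x band RMS amplitudes (microvolt), bands delta/theta/alpha/sigma/beta.
DEFAULT_BAND_AMPLITUDES: np.ndarray = np.array(
    [
        # delta theta alpha sigma beta
        [5.0, 5.0, 20.0, 3.0, 8.0],   # W: posterior alpha rhythm
        [8.0, 18.0, 6.0, 3.0, 4.0],   # N1: low-amplitude theta
        [12.0, 8.0, 5.0, 18.0, 3.0],  # N2: sigma/spindle activity
        [30.0, 8.0, 4.0, 4.0, 2.0],   # N3: high-amplitude slow waves
        [6.0, 15.0, 5.0, 3.0, 12.0],  # REM: mixed theta + beta
    ]
)
DEFAULT_BAND_AMPLITUDES.setflags(write=False)


def _default_transition() -> np.ndarray:
    return DEFAULT_TRANSITION_MATRIX.copy()


def _default_amplitudes() -> np.ndarray:
    return DEFAULT_BAND_AMPLITUDES.copy()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated recording.

    Defaults give a 6-channel, 2000-epoch (about 16.7 h), 100 Hz recording
    with the sleep-architecture occupancies described in the module
    docstring.
    """

    n_channels: int = 6
    n_epochs: int = 2000
    sampling_rate: float = 100.0
    epoch_length_s: float = 30.0
    transition_matrix: np.ndarray = field(default_factory=_default_transition, repr=False)
    stage_band_amplitudes: np.ndarray = field(default_factory=_default_amplitudes, repr=False)
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    noise_sd: float = 5.0
    channel_gain_sd: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (N_STAGES, N_STAGES):
            raise ValidationError("transition_matrix must be 5x5")
        if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition_matrix rows must sum to 1")
        amp = np.asarray(self.stage_band_amplitudes, dtype=float)
        if amp.shape != (N_STAGES, len(self.band_edges)):
            raise ValidationError(
                f"stage_band_amplitudes must be (5, {len(self.band_edges)})"
            )
        if np.any(amp < 0):
            raise ValidationError("band amplitudes must be nonnegative")
        if self.n_epochs < 1:
            raise ValidationError("n_epochs must be >= 1")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "stage_band_amplitudes", amp)
        object.__setattr__(
            self, "band_edges", tuple(tuple(b) for b in self.band_edges)
        )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_length_s))

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_epochs": self.n_epochs,
            "sampling_rate": self.sampling_rate,
            "epoch_length_s": self.epoch_length_s,
            "transition_matrix": np.asarray(self.transition_matrix).tolist(),
            "stage_band_amplitudes": np.asarray(self.stage_band_amplitudes).tolist(),
            "band_edges": [list(b) for b in self.band_edges],
            "noise_sd": self.noise_sd,
            "channel_gain_sd": self.channel_gain_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        payload = dict(payload)
        if "transition_matrix" in payload:
            payload["transition_matrix"] = np.asarray(payload["transition_matrix"])
        if "stage_band_amplitudes" in payload:
            payload["stage_band_amplitudes"] = np.asarray(
                payload["stage_band_amplitudes"]
            )
        if "band_edges" in payload:
            payload["band_edges"] = tuple(tuple(b) for b in payload["band_edges"])
        return cls(**payload)


@dataclass(frozen=True)
class LabeledRecording:
    """A simulated hypnogram-labeled epoch sequence with node features.

    ``features`` has shape (n_epochs, n_channels, n_bands); ``labels`` are
    stage indices in the canonical order W, N1, N2, N3, REM.  Contiguous
    70/15/15 train/validation/test index blocks are attached.
    """

    features: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    config: SimulationConfig
    train_idx: np.ndarray = field(repr=False)
    val_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int64)
        if feats.shape[0] != labels.shape[0]:
            raise ValidationError("features and labels must align on epochs")
        if np.any((labels < 0) | (labels >= N_STAGES)):
            raise ValidationError("labels must be stage indices 0..4")
        if not np.all(np.isfinite(feats)):
            raise ValidationError("features must be finite")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    def stage_occupancy(self) -> np.ndarray:
        """Fraction of epochs in each stage (canonical order)."""
        return np.bincount(self.labels, minlength=N_STAGES) / self.n_epochs


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized to sum 1)."""
    tm = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(tm.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(config: SimulationConfig) -> np.ndarray:
    """Sample a stage-label sequence from the first-order Markov chain.

    The chain starts from the stationary distribution of the transition
    matrix and is fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    return _simulate_hypnogram(config, rng)


def _simulate_hypnogram(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    tm = config.transition_matrix
    pi = stationary_distribution(tm)
    labels = np.empty(config.n_epochs, dtype=np.int64)
    labels[0] = rng.choice(N_STAGES, p=pi)
    for t in range(1, config.n_epochs):
        labels[t] = rng.choice(N_STAGES, p=tm[labels[t - 1]])
    return labels


def synthesize_epoch_signal(
    stage: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One epoch of multichannel signal for a given stage.

    Per band: a sinusoid at a frequency drawn uniformly inside the band
    (shared across channels), with the stage's RMS amplitude, a random
    phase per channel, and per-channel gain jitter ``1 + N(0, gain_sd)``.
    White noise of sd ``noise_sd`` is added throughout.  Returns
    ``(n_channels, epoch_samples)`` microvolts.
    """
    if not 0 <= stage < N_STAGES:
        raise ValidationError(f"stage must be 0..4, got {stage}")
    n_ch = config.n_channels
    length = config.epoch_samples
    t = np.arange(length) / config.sampling_rate
    gains = 1.0 + rng.normal(0.0, config.channel_gain_sd, size=n_ch)
    signal = np.zeros((n_ch, length))
    for b, (low, high) in enumerate(config.band_edges):
        rms = config.stage_band_amplitudes[stage, b]
        freq = rng.uniform(low, high)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
        if rms > 0:
            amp = rms * np.sqrt(2.0)  # sinusoid RMS = amplitude / sqrt(2)
            signal += amp * np.sin(
                2.0 * np.pi * freq * t[None, :] + phases[:, None]
            )
    signal *= gains[:, None]
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=(n_ch, length))
    return signal


def generate_dataset(
    config: SimulationConfig,
    mode: Literal["features", "signal"] = "features",
) -> LabeledRecording:
    """Simulate a full labeled recording.

    A single seeded RNG stream drives the hypnogram and then each epoch's
    signal in order, so the whole dataset is reproducible from the config.
    In ``"features"`` mode (default) only band-log-power node features are
    kept; ``"signal"`` mode stores the raw signal concatenated over epochs
    in ``features`` of shape (n_epochs, n_channels, epoch_samples).
    """
    rng = np.random.default_rng(config.seed)
    labels = _simulate_hypnogram(config, rng)
    per_epoch = []
    for lab in labels:
        sig = synthesize_epoch_signal(int(lab), config, rng)
        if mode == "features":
            per_epoch.append(
                band_log_power(sig, config.sampling_rate, config.band_edges)
            )
        else:
            per_epoch.append(sig)
    features = np.stack(per_epoch)

    n = config.n_epochs
    n_train = int(0.70 * n)
    n_val = int(0.85 * n) - n_train
    idx = np.arange(n)
    return LabeledRecording(
        features=features,
        labels=labels,
        config=config,
        train_idx=idx[:n_train],
        val_idx=idx[n_train : n_train + n_val],
        test_idx=idx[n_train + n_val :],
    )
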