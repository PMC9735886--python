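"""Epoch segmentation and spectral node features.

Raw multichannel signals are cut into fixed-length scoring epochs (30 s by
convention) and each channel of each epoch is summarized by log band powers
in the standard sleep-EEG bands.  These per-channel feature vectors are the
node features consumed by both the spatial (graph) and temporal (recurrent)
branches of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import periodogram

from .exceptions import ParameterError, ValidationError

__all__ = [
    "RawRecording",
    "EpochFeatureSequence",
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "segment_epochs",
    "band_log_power",
    "extract_features",
    "zscore_features",
    "save_features",
    "load_features",
    "features_to_csv",
]

# Standard sleep-EEG frequency bands (Hz): delta, theta, alpha, sigma, beta.
# Sigma (11-16 Hz) overlaps alpha deliberately - it is the spindle band.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 13.0),
    (11.0, 16.0),
    (16.0, 30.0),
)
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "sigma", "beta")

_EPS = 1e-12


@dataclass(frozen=True)
class RawRecording:
    """A multichannel signal in microvolts.

    ``signal`` has shape ``(n_channels, n_samples)``.
    """

    signal: np.ndarray = field(repr=False)
    sampling_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValidationError(f"signal must be 2D, got shape {sig.shape}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.channel_names) != sig.shape[0]:
            raise ValidationError("channel_names length must match signal rows")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class EpochFeatureSequence:
    """Per-epoch, per-channel node feature vectors.

    ``features`` has shape ``(n_epochs, n_channels, n_features)``; when
    produced by :func:`band_log_power` the feature axis indexes
    ``band_edges``.
    """

    features: np.ndarray = field(repr=False)
    epoch_length_s: float = 30.0
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 3:
            raise ValidationError(f"features must be 3D, got shape {feats.shape}")
        if not np.all(np.isfinite(feats)):
            raise ValidationError("features must be finite")
        object.__setattr__(self, "features", feats)
        object.__setattr__(
            self, "band_edges", tuple(tuple(b) for b in self.band_edges)
        )

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]


def segment_epochs(rec: RawRecording, epoch_length_s: float = 30.0) -> list[np.ndarray]:
    """Split a recording into non-overlapping epochs of fixed length.

    Each segment has shape ``(n_channels, L)`` with
    ``L = round(sampling_rate * epoch_length_s)``; a trailing partial epoch
    is dropped.
    """
    if epoch_length_s <= 0:
        raise ParameterError("epoch_length_s must be positive")
    length = int(round(rec.sampling_rate * epoch_length_s))
    n_samples = rec.signal.shape[1]
    n_epochs = n_samples // length
    if n_epochs == 0:
        raise ValidationError(
            f"recording has {n_samples} samples, shorter than one "
            f"{length}-sample epoch"
        )
    return [
        rec.signal[:, i * length : (i + 1) * length] for i in range(n_epochs)
    ]


def band_log_power(
    segment: np.ndarray,
    sampling_rate: float,
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    window: str = "boxcar",
) -> np.ndarray:
    """Log mean periodogram power per frequency band.

    For each channel row, the mean-removed segment's periodogram is averaged
    over the bins falling in each band ``[low, high)`` and the feature is
    ``log(eps + mean_power)`` with ``eps = 1e-12``.  A band that contains no
    frequency bin at this segment length is a parameter error.

    Parameters
    ----------
    segment
        ``(n_channels, L)`` signal block, microvolts.
    sampling_rate
        Sampling frequency, Hz.
    band_edges
        ``(low, high)`` pairs in Hz; must lie in ``(0, sampling_rate / 2)``.
    window
        Taper passed to the periodogram; ``"boxcar"`` (none) by default,
        ``"hann"`` available.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise ParameterError(f"segment must be 2D, got shape {segment.shape}")
    nyquist = sampling_rate / 2.0
    for low, high in band_edges:
        if not (0.0 < low < high <= nyquist):
            raise ParameterError(
                f"band ({low}, {high}) outside (0, {nyquist}] or inverted"
            )
    freqs, psd = periodogram(
        segment, fs=sampling_rate, window=window, detrend="constant", axis=-1
    )
    out = np.empty((segment.shape[0], len(band_edges)))
    for b, (low, high) in enumerate(band_edges):
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ParameterError(
                f"band ({low}, {high}) Hz contains no frequency bins at "
                f"segment length {segment.shape[1]}"
            )
        out[:, b] = np.log(_EPS + psd[:, mask].mean(axis=-1))
    return out


def extract_features(
    rec: RawRecording,
    epoch_length_s: float = 30.0,
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    window: str = "boxcar",
) -> EpochFeatureSequence:
    """Segment a recording and compute band-log-power node features."""
    segments = segment_epochs(rec, epoch_length_s)
    feats = np.stack(
        [band_log_power(s, rec.sampling_rate, band_edges, window) for s in segments]
    )
    return EpochFeatureSequence(
        features=feats, epoch_length_s=epoch_length_s, band_edges=band_edges
    )


def zscore_features(features: np.ndarray) -> np.ndarray:
    """Standardize each (channel, feature) series across epochs.

    Zero-variance series are left centered at 0 rather than divided by 0.
    """
    features = np.asarray(features, dtype=float)
    mean = features.mean(axis=0, keepdims=True)
    std = features.std(axis=0, keepdims=True)
    std = np.where(std > 0, std, 1.0)
    return (features - mean) / std


def save_features(
    path: str | Path,
    features: np.ndarray,
    labels: np.ndarray,
    channel_names: tuple[str, ...],
) -> None:
    """Save features, labels and channel names to an ``.npz`` container."""
    np.savez(
        path,
        features=np.asarray(features, dtype=float),
        labels=np.asarray(labels, dtype=np.int64),
        channel_names=np.array(list(channel_names)),
    )


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Load the ``.npz`` container written by :func:`save_features`."""
    with np.load(path, allow_pickle=False) as data:
        return (
            data["features"],
            data["labels"],
            tuple(str(c) for c in data["channel_names"]),
        )


def features_to_csv(
    path: str | Path,
    features: np.ndarray,
    channel_names: tuple[str, ...],
    feature_names: tuple[str, ...] | None = None,
) -> None:
    """Export features as CSV, one row per (epoch, channel)."""
    import pandas as pd

    features = np.asarray(features)
    n_epochs, n_channels, n_feats = features.shape
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(n_feats))
    rows = features.reshape(n_epochs * n_channels, n_feats)
    frame = pd.DataFrame(rows, columns=list(feature_names))
    frame.insert(0, "channel", list(channel_names) * n_epochs)
    frame.insert(0, "epoch", np.repeat(np.arange(n_epochs), n_channels))
    frame.to_csv(path, index=False)
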