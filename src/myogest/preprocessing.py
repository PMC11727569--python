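"""Raw sEMG conditioning: band-pass filtering, per-channel Z-score, windowing.

The pipeline turns a continuous multichannel recording into a stack of
``L x T x 1`` single-feature-channel "grayscale images": the signal is
band-pass filtered (the useful sEMG energy lives roughly between 10 and
500 Hz), each electrode channel is standardised independently, and a
sliding window of length ``w`` ms advancing by ``s`` ms cuts the stream
into window images with ``L = w * f / 1000`` time samples per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "FilterSpec",
    "FilterMode",
    "ChannelStats",
    "WindowSpec",
    "WindowedDataset",
    "window_length",
    "bandpass_filter",
    "fit_normalizer",
    "apply_normalizer",
    "segment_windows",
    "design_sos",
    "NYQUIST_MARGIN",
]

# A digital band edge sitting on Nyquist is ill-defined; when the configured
# upper cutoff reaches it, clamp to this fraction of the sampling rate.
NYQUIST_MARGIN = 0.45


class FilterMode(str, Enum):
    """Zero-phase filtering for offline training data, causal for streams."""

    offline_zero_phase = "offline_zero_phase"
    causal_streaming = "causal_streaming"


@dataclass(frozen=True)
class RawRecording:
    """A continuous multichannel sEMG recording with per-sample annotations.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, T)
        Electrode voltages in microvolts (or standardised units after
        normalisation).
    f : float
        Sampling frequency in Hz.
    labels : ndarray of int, shape (n_samples,)
        0 for rest, ``1..M`` for the active gesture class.
    repetitions : ndarray of int, shape (n_samples,)
        0 for rest, otherwise the repetition index of the active gesture.
    subject_id : str
        Free-form subject identifier.
    """

    signal: np.ndarray
    f: float
    labels: np.ndarray
    repetitions: np.ndarray
    subject_id: str = "S?"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 2 or sig.shape[1] < 1:
            raise ValueError("signal must be a 2-D (n_samples, T) array with T >= 1")
        labels = np.asarray(self.labels, dtype=np.int64)
        reps = np.asarray(self.repetitions, dtype=np.int64)
        if not (len(labels) == len(reps) == sig.shape[0]):
            raise ValueError("labels and repetitions must align sample-by-sample with signal")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative integers")
        if self.f <= 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "repetitions", reps)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    def replace_signal(self, new_signal: np.ndarray) -> "RawRecording":
        return RawRecording(new_signal, self.f, self.labels, self.repetitions, self.subject_id)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass configuration (default: 4th order, 10-500 Hz)."""

    order: int = 4
    low_hz: float = 10.0
    high_hz: float = 500.0
    mode: FilterMode = FilterMode.offline_zero_phase

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and population standard deviation for Z-scoring."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=np.float64).ravel()
        sigma = np.asarray(self.sigma, dtype=np.float64).ravel()
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have the same length")
        bad = np.flatnonzero(~(sigma > 0))
        if bad.size:
            raise ValueError(f"degenerate (constant) channel(s) {bad.tolist()}: sigma must be > 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_channels(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window length and step, both in milliseconds."""

    w_ms: float = 200.0
    s_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.w_ms <= 0:
            raise ValueError("window length must be positive")
        if not 0 < self.s_ms <= self.w_ms:
            raise ValueError("step must satisfy 0 < s_ms <= w_ms")


@dataclass
class WindowedDataset:
    """Stack of window images with one label and repetition id per window.

    ``images`` has shape ``(N, L, T, 1)`` — time axis, electrode axis, and a
    single feature channel, ready for 2-D convolution.
    """

    images: np.ndarray
    labels: np.ndarray
    repetitions: np.ndarray
    w_ms: float
    s_ms: float
    f: float
    subject_id: str = "S?"

    def __post_init__(self) -> None:
        img = np.asarray(self.images, dtype=np.float64)
        if img.ndim != 4 or img.shape[3] != 1:
            raise ValueError("images must have shape (N, L, T, 1)")
        L = window_length(self.w_ms, self.f)
        if img.shape[0] and img.shape[1] != L:
            raise ValueError(f"image time dimension {img.shape[1]} != L={L} from (w_ms, f)")
        self.images = img
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetitions = np.asarray(self.repetitions, dtype=np.int64)
        if not (len(self.labels) == len(self.repetitions) == img.shape[0]):
            raise ValueError("labels/repetitions must have one entry per window")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple:
        return self.images.shape[1:]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.images[idx], self.labels[idx], self.repetitions[idx],
            self.w_ms, self.s_ms, self.f, self.subject_id,
        )


def window_length(w_ms: float, f_hz: float) -> int:
    """Number of time samples per window: ``L = w * f / 1000``.

    Raises ``ValueError`` when the product is not a whole number of samples.
    """
    if w_ms <= 0 or f_hz <= 0:
        raise ValueError("w_ms and f_hz must be positive")
    exact = w_ms * f_hz / 1000.0
    L = round(exact)
    if L < 1 or abs(exact - L) > 1e-9:
        raise ValueError(
            f"window of {w_ms} ms at {f_hz} Hz gives a non-integer sample count {exact}"
        )
    return int(L)


def effective_band(spec: FilterSpec, f_hz: float) -> tuple:
    """Clamp the upper band edge away from Nyquist; error if the band collapses."""
    high = spec.high_hz
    limit = NYQUIST_MARGIN * f_hz
    if high >= f_hz / 2.0:
        logger.warning(
            "band-pass upper edge %.1f Hz >= Nyquist (%.1f Hz); clamping to %.1f Hz",
            high, f_hz / 2.0, limit,
        )
        high = limit
    if spec.low_hz >= high:
        raise ValueError(
            f"band collapsed: low {spec.low_hz} Hz >= effective high {high} Hz at f={f_hz} Hz"
        )
    return spec.low_hz, high


def design_sos(spec: FilterSpec, f_hz: float) -> np.ndarray:
    """Second-order-section coefficients for the band-pass at this rate."""
    low, high = effective_band(spec, f_hz)
    return sps.butter(spec.order, [low, high], btype="bandpass", fs=f_hz, output="sos")


def bandpass_filter(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Band-pass filter every channel independently.

    Offline mode uses zero-phase forward-backward filtering so the window
    images fed to training carry no phase distortion; causal mode applies
    the same coefficients in a single forward pass, matching what a live
    stream can compute.
    """
    if not np.all(np.isfinite(rec.signal)):
        raise ValueError("signal contains non-finite values")
    sos = design_sos(spec, rec.f)
    if spec.mode is FilterMode.offline_zero_phase:
        out = sps.sosfiltfilt(sos, rec.signal, axis=0)
    else:
        out = sps.sosfilt(sos, rec.signal, axis=0)
    return rec.replace_signal(np.ascontiguousarray(out))


def fit_normalizer(rec: RawRecording) -> ChannelStats:
    """Per-channel mean and population standard deviation over all samples."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to fit a normalizer")
    mu = rec.signal.mean(axis=0)
    sigma = rec.signal.std(axis=0)  # population (ddof=0)
    return ChannelStats(mu, sigma)


def apply_normalizer(rec: RawRecording, stats: ChannelStats) -> RawRecording:
    """Z-score each channel: ``z = (x - mu) / sigma``; annotations untouched."""
    if stats.n_channels != rec.n_channels:
        raise ValueError(
            f"normalizer has {stats.n_channels} channels, recording has {rec.n_channels}"
        )
    return rec.replace_signal((rec.signal - stats.mu) / stats.sigma)


def _step_samples(s_ms: float, f_hz: float) -> int:
    exact = s_ms * f_hz / 1000.0
    S = round(exact)
    if S < 1 or abs(exact - S) > 1e-9:
        raise ValueError(f"step of {s_ms} ms at {f_hz} Hz gives a non-integer stride {exact}")
    return int(S)


def majority_label(window_labels: np.ndarray) -> int:
    """Modal per-sample label of a window; ties break toward the larger class."""
    counts = np.bincount(window_labels)
    best = counts.max()
    return int(np.flatnonzero(counts == best)[-1])


def segment_windows(
    rec: RawRecording,
    wspec: WindowSpec,
    keep_rest: bool = False,
) -> WindowedDataset:
    """Cut a (filtered, normalised) recording into L x T x 1 window images.

    Windows start at samples ``0, S, 2S, ...`` and cover the half-open range
    ``[start, start + L)``. Each window takes the majority per-sample label;
    ties break toward the larger class index, and rest-majority windows are
    dropped unless ``keep_rest``. The repetition id is the majority repetition
    among the window's active samples (0 for rest windows).
    """
    L = window_length(wspec.w_ms, rec.f)
    S = _step_samples(wspec.s_ms, rec.f)
    n = rec.n_samples
    if n < L:
        empty = np.empty((0, L, rec.n_channels, 1))
        return WindowedDataset(empty, [], [], wspec.w_ms, wspec.s_ms, rec.f, rec.subject_id)

    starts = np.arange(0, n - L + 1, S)
    # (n-L+1, T, L) view -> pick strided starts -> (N, L, T)
    view = np.lib.stride_tricks.sliding_window_view(rec.signal, L, axis=0)
    images = view[starts].transpose(0, 2, 1)[..., np.newaxis]

    lab_view = np.lib.stride_tricks.sliding_window_view(rec.labels, L)[starts]
    rep_view = np.lib.stride_tricks.sliding_window_view(rec.repetitions, L)[starts]

    labels = np.fromiter((majority_label(w) for w in lab_view), dtype=np.int64, count=len(starts))
    reps = np.empty(len(starts), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab == 0:
            reps[i] = 0
        else:
            active = rep_view[i][lab_view[i] == lab]
            reps[i] = majority_label(active) if active.size else 0

    if not keep_rest:
        keep = labels > 0
        images, labels, reps = images[keep], labels[keep], reps[keep]

    return WindowedDataset(
        np.ascontiguousarray(images), labels, reps,
        wspec.w_ms, wspec.s_ms, rec.f, rec.subject_id,
    )
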