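"""Synthetic multichannel sEMG generator.

Emulates a typical armband acquisition protocol: each gesture class is
re-executed for several repetitions, each repetition contributing a rest
interval followed by an active interval, with per-sample gesture labels
and repetition indices. The active signal is a band-limited Gaussian
carrier (sEMG energy sits mostly between 10 and 500 Hz) shaped by a
smooth envelope and a gesture-specific per-channel gain pattern, with
microvolt-scale amplitudes, additive white noise at a configurable SNR,
sinusoidal power-line interference and slow baseline drift — the three
noise sources band-pass filtering is meant to suppress.

This is deliberately not a biophysical motor-unit simulation: the
downstream method only assumes band-limited, channel-patterned activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .preprocessing import RawRecording

__all__ = ["GestureProfile", "SynthConfig", "make_profiles", "generate_recording"]

#: minimum per-channel gain contrast between any two gesture profiles
MIN_GAIN_SEPARATION = 0.3


@dataclass(frozen=True)
class GestureProfile:
    """Which channels a gesture activates and with what carrier band."""

    class_id: int
    channel_gains: np.ndarray
    envelope_shape: str = "plateau"  # or "ramp"
    burst_band: Tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        gains = np.asarray(self.channel_gains, dtype=np.float64)
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")
        if gains.ndim != 1 or not np.all((gains > 0) & (gains <= 1)):
            raise ValueError("channel_gains must be a vector with entries in (0, 1]")
        if not np.any(gains > 0.5):
            raise ValueError("a gesture must strongly activate at least one channel")
        if self.envelope_shape not in ("plateau", "ramp"):
            raise ValueError("envelope_shape must be 'plateau' or 'ramp'")
        object.__setattr__(self, "channel_gains", gains)


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition-protocol and noise parameters for one synthetic recording.

    Defaults follow the common protocol for this kind of dataset: each
    gesture held for 5 s with a 3 s rest, 5 repetitions, 8 electrode
    channels at 1000 Hz, amplitudes on the 15-100 uV scale.
    """

    n_classes: int = 6
    T: int = 8
    f: float = 1000.0
    reps: int = 5
    active_s: float = 5.0
    rest_s: float = 3.0
    base_amp_uv: float = 60.0
    snr_db: float = 25.0
    line_hz: float = 50.0
    line_amp_uv: float = 2.0
    drift_amp_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 gesture classes")
        if self.reps < 2:
            raise ValueError("need at least 2 repetitions")
        if self.active_s <= 0 or self.rest_s <= 0:
            raise ValueError("active_s and rest_s must be positive")
        if self.T < 1 or self.f <= 0:
            raise ValueError("invalid channel count or sampling rate")


def make_profiles(n_classes: int, T: int, seed: int = 0) -> List[GestureProfile]:
    """Deterministic, pairwise-separable gesture activation profiles.

    Each class gets a distinct binary on/off channel mask (at least one
    channel on); "on" channels draw gains in [0.7, 1.0] and "off" channels
    in [0.05, 0.3], so any two classes differ by >= 0.4 > MIN_GAIN_SEPARATION
    in at least one channel.
    """
    capacity = 2 ** T - 1  # all-off pattern excluded
    if n_classes > capacity:
        raise ValueError(
            f"cannot build {n_classes} separable profiles on {T} channels "
            f"(at most {capacity} distinct activation masks)"
        )
    rng = np.random.default_rng([seed, T, n_classes])
    masks: list = []
    seen = set()
    while len(masks) < n_classes:
        m = tuple(int(b) for b in rng.integers(0, 2, size=T))
        if sum(m) == 0 or m in seen:
            continue
        seen.add(m)
        masks.append(np.array(m, dtype=bool))
    profiles = []
    for cid, mask in enumerate(masks, start=1):
        gains = np.where(
            mask,
            rng.uniform(0.7, 1.0, size=T),
            rng.uniform(0.05, 0.3, size=T),
        )
        profiles.append(GestureProfile(class_id=cid, channel_gains=gains))
    return profiles


def _envelope(n: int, f: float, shape: str) -> np.ndarray:
    """Plateau (or ramp) envelope with 100 ms raised-cosine edges."""
    ramp = min(int(0.1 * f), n // 2)
    env = np.ones(n)
    if shape == "ramp":
        env = np.linspace(0.3, 1.0, n)
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] *= up
        env[-ramp:] *= up[::-1]
    return env


def _band_limited_noise(rng: np.random.Generator, n: int, T: int, f: float,
                        band: Tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * f)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=f, output="sos")
    white = rng.standard_normal((n, T))
    x = sps.sosfiltfilt(sos, white, axis=0)
    # unit RMS per channel so base_amp_uv sets the scale directly
    rms = np.sqrt(np.mean(x ** 2, axis=0))
    return x / rms


def _baseline_drift(rng: np.random.Generator, n: int, T: int, f: float,
                    amp_uv: float) -> np.ndarray:
    """Slow (< ~1 Hz) wandering baseline with the requested RMS amplitude."""
    if amp_uv <= 0:
        return np.zeros((n, T))
    sos = sps.butter(2, 1.0, btype="lowpass", fs=f, output="sos")
    walk = sps.sosfiltfilt(sos, rng.standard_normal((n, T)), axis=0)
    rms = np.sqrt(np.mean(walk ** 2, axis=0))
    rms[rms == 0] = 1.0
    return walk / rms * amp_uv


def generate_recording(
    cfg: SynthConfig,
    profiles: Sequence[GestureProfile] | None = None,
    subject_index: int = 0,
    subject_id: str | None = None,
) -> RawRecording:
    """Generate one labelled recording following the repetition protocol.

    For each repetition ``r = 1..reps`` and each class in order the stream
    holds ``rest_s`` seconds of rest (label 0, repetition 0) followed by
    ``active_s`` seconds of the class's activity (label = class id,
    repetition = r). Deterministic given (cfg.seed, subject_index).
    """
    if profiles is None:
        profiles = make_profiles(cfg.n_classes, cfg.T, cfg.seed)
    if len(profiles) != cfg.n_classes:
        raise ValueError(f"expected {cfg.n_classes} profiles, got {len(profiles)}")

    rng = np.random.default_rng([cfg.seed, subject_index])
    f, T = cfg.f, cfg.T
    n_active = int(round(cfg.active_s * f))
    n_rest = int(round(cfg.rest_s * f))
    n_block = n_rest + n_active
    n_total = cfg.reps * cfg.n_classes * n_block

    clean = np.zeros((n_total, T))
    labels = np.zeros(n_total, dtype=np.int64)
    reps = np.zeros(n_total, dtype=np.int64)

    pos = 0
    for r in range(1, cfg.reps + 1):
        for prof in profiles:
            a0 = pos + n_rest
            carrier = _band_limited_noise(rng, n_active, T, f, prof.burst_band)
            env = _envelope(n_active, f, prof.envelope_shape)
            clean[a0:a0 + n_active] = (
                carrier * env[:, None] * prof.channel_gains[None, :] * cfg.base_amp_uv
            )
            labels[a0:a0 + n_active] = prof.class_id
            reps[a0:a0 + n_active] = r
            pos += n_block

    active = labels > 0
    clean_rms = np.sqrt(np.mean(clean[active] ** 2))
    noise_std = clean_rms * 10 ** (-cfg.snr_db / 20.0)
    noise = rng.standard_normal((n_total, T)) * noise_std

    t = np.arange(n_total) / f
    phases = rng.uniform(0, 2 * np.pi, size=T)
    line = cfg.line_amp_uv * np.sin(2 * np.pi * cfg.line_hz * t[:, None] + phases[None, :])

    drift = _baseline_drift(rng, n_total, T, f, cfg.drift_amp_uv)

    sid = subject_id if subject_id is not None else f"SYN{subject_index}"
    return RawRecording(clean + noise + line + drift, f, labels, reps, subject_id=sid)
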