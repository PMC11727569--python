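"""Filtering, normalisation and windowing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from myogest.preprocessing import (
    ChannelStats, FilterMode, FilterSpec, RawRecording, WindowSpec,
    apply_normalizer, bandpass_filter, fit_normalizer, majority_label,
    segment_windows, window_length,
)


def make_rec(signal, f=1000.0, labels=None, reps=None):
    n = len(signal)
    labels = np.ones(n, dtype=int) if labels is None else labels
    reps = np.ones(n, dtype=int) if reps is None else reps
    return RawRecording(np.atleast_2d(signal.T).T if signal.ndim == 1 else signal,
                        f, labels, reps)


# -- window_length --------------------------------------------------------

@pytest.mark.parametrize("w_ms,f,expected", [
    (200, 2000, 400),   # benchmark preprocessing settings
    (100, 1000, 100),   # armband streaming settings
    (1000, 1000, 1000),
])
def test_window_length_grid(w_ms, f, expected):
    assert window_length(w_ms, f) == expected


def test_window_length_rejects_fractional_samples():
    with pytest.raises(ValueError):
        window_length(150, 990)
    with pytest.raises(ValueError):
        window_length(-5, 1000)


# -- band-pass filter -----------------------------------------------------

def test_filter_preserves_zero_signal():
    rec = make_rec(np.zeros((500, 2)))
    out = bandpass_filter(rec, FilterSpec())
    np.testing.assert_allclose(out.signal, 0.0)


def test_filter_stopband_attenuation_on_seeded_noise():
    """Power left in [2, 5] Hz must be <= 0.1x the power in [80, 120] Hz."""
    rng = np.random.default_rng(123)
    f = 2000.0
    x = rng.standard_normal((int(12 * f), 1))
    out = bandpass_filter(make_rec(x, f=f), FilterSpec())
    freqs, psd = sps.periodogram(out.signal[:, 0], fs=f)
    low = psd[(freqs >= 2) & (freqs <= 5)].mean()
    mid = psd[(freqs >= 80) & (freqs <= 120)].mean()
    assert low <= 0.1 * mid


def test_filter_passband_rms_midband_sinusoid():
    f = 2000.0
    t = np.arange(int(4 * f)) / f
    x = np.sin(2 * np.pi * 100 * t)[:, None]
    out = bandpass_filter(make_rec(x, f=f), FilterSpec())
    core = slice(int(f), int(3 * f))  # avoid edge transients
    rms_in = np.sqrt(np.mean(x[core] ** 2))
    rms_out = np.sqrt(np.mean(out.signal[core] ** 2))
    assert abs(rms_out - rms_in) / rms_in < 0.05


def test_filter_linearity_per_channel():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((2000, 2))
    y = rng.standard_normal((2000, 2))
    spec = FilterSpec()
    fx = bandpass_filter(make_rec(x), spec).signal
    fy = bandpass_filter(make_rec(y), spec).signal
    fxy = bandpass_filter(make_rec(2.5 * x - 1.5 * y), spec).signal
    np.testing.assert_allclose(fxy, 2.5 * fx - 1.5 * fy, atol=1e-9)


def test_nyquist_clamp_and_collapse():
    # 500 Hz edge at f=1000 Hz sits on Nyquist: clamped, not an error
    rec = make_rec(np.random.default_rng(0).standard_normal((2000, 1)), f=1000.0)
    bandpass_filter(rec, FilterSpec())
    with pytest.raises(ValueError):
        bandpass_filter(rec, FilterSpec(low_hz=460.0, high_hz=500.0))


def test_causal_mode_is_causal():
    """An impulse at sample k produces no output before k in causal mode."""
    x = np.zeros((1000, 1))
    x[500] = 1.0
    out = bandpass_filter(make_rec(x), FilterSpec(mode=FilterMode.causal_streaming))
    np.testing.assert_allclose(out.signal[:500], 0.0, atol=1e-15)


# -- normalisation --------------------------------------------------------

def test_fit_normalizer_hand_example():
    rec = make_rec(np.array([[1.0], [2.0], [3.0]]))
    stats = fit_normalizer(rec)
    assert stats.mu[0] == pytest.approx(2.0)
    assert stats.sigma[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-4)
    z = apply_normalizer(rec, stats).signal[:, 0]
    np.testing.assert_allclose(z, [-1.224745, 0.0, 1.224745], atol=1e-6)


def test_fit_normalizer_rejects_constant_channel():
    rec = make_rec(np.column_stack([np.arange(5.0), np.full(5, 5.0)]))
    with pytest.raises(ValueError, match="1"):
        fit_normalizer(rec)


def test_normalizer_roundtrip_and_scale_invariance():
    rng = np.random.default_rng(9)
    sig = rng.standard_normal((4000, 2)) * np.array([1.0, 100.0]) + np.array([5.0, -3.0])
    rec = make_rec(sig)
    z = apply_normalizer(rec, fit_normalizer(rec)).signal
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)
    # 100x amplitude ratio disappears
    assert z[:, 1].std() / z[:, 0].std() == pytest.approx(1.0, abs=1e-12)


def test_identity_stats_are_identity():
    rec = make_rec(np.random.default_rng(1).standard_normal((100, 3)))
    out = apply_normalizer(rec, ChannelStats(np.zeros(3), np.ones(3)))
    np.testing.assert_array_equal(out.signal, rec.signal)


def test_apply_normalizer_channel_mismatch():
    rec = make_rec(np.random.default_rng(1).standard_normal((100, 3)))
    with pytest.raises(ValueError):
        apply_normalizer(rec, ChannelStats(np.zeros(2), np.ones(2)))


# -- windowing ------------------------------------------------------------

def test_segment_window_count_and_shape():
    rng = np.random.default_rng(2)
    rec = make_rec(rng.standard_normal((1000, 3)), f=2000.0)
    ds = segment_windows(rec, WindowSpec(200, 50))
    # L=400, S=100 -> floor((1000-400)/100)+1 = 7
    assert ds.images.shape == (7, 400, 3, 1)
    np.testing.assert_array_equal(ds.labels, 1)


def test_segment_exact_length_gives_one_window():
    rec = make_rec(np.random.default_rng(3).standard_normal((400, 2)), f=2000.0)
    ds = segment_windows(rec, WindowSpec(200, 50))
    assert len(ds) == 1


def test_segment_shorter_than_window_is_empty():
    rec = make_rec(np.random.default_rng(3).standard_normal((100, 2)), f=2000.0)
    assert len(segment_windows(rec, WindowSpec(200, 50))) == 0


def test_majority_labeling_and_rest_dropping():
    n = 100
    labels = np.zeros(n, dtype=int)
    labels[:40] = 1
    labels[40:] = 3  # 60% label 3
    rec = make_rec(np.random.default_rng(4).standard_normal((n, 2)),
                   f=1000.0, labels=labels, reps=np.ones(n, dtype=int))
    ds = segment_windows(rec, WindowSpec(100, 100))
    assert list(ds.labels) == [3]

    rest = make_rec(np.random.default_rng(4).standard_normal((n, 2)),
                    f=1000.0, labels=np.zeros(n, dtype=int),
                    reps=np.zeros(n, dtype=int))
    assert len(segment_windows(rest, WindowSpec(100, 100))) == 0
    kept = segment_windows(rest, WindowSpec(100, 100), keep_rest=True)
    assert list(kept.labels) == [0]


def test_majority_label_tie_breaks_to_larger_class():
    assert majority_label(np.array([1, 1, 2, 2])) == 2


def test_non_overlapping_windows_tile_signal():
    rec = make_rec(np.arange(600, dtype=float).reshape(600, 1), f=1000.0)
    ds = segment_windows(rec, WindowSpec(100, 100))
    flat = ds.images[:, :, 0, 0].ravel()
    np.testing.assert_array_equal(flat, np.arange(600.0))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    n=st.integers(min_value=50, max_value=1500),
    L=st.sampled_from([20, 50, 100]),
    S=st.sampled_from([10, 20, 50]),
)
def test_window_count_property(n, L, S):
    if S > L:
        S = L
    rec = make_rec(np.zeros((n, 1)) + np.random.default_rng(0).standard_normal((n, 1)),
                   f=1000.0)
    ds = segment_windows(rec, WindowSpec(L, S), keep_rest=True)
    expected = 0 if n < L else (n - L) // S + 1
    assert len(ds) == expected
    assert ds.images.shape[1:] == (L, 1, 1)
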