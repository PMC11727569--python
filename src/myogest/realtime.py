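"""Causal streaming inference with majority-vote smoothing.

A live classifier emits one frame-level prediction per window step; at
15-ish frames per second a stream accumulates misclassifications that
would twitch a prosthesis or manipulator. The majority-voting window
keeps the last ``V`` frame predictions in a FIFO buffer and re-emits the
modal label every frame, trading a little latency for stability.

Streaming uses the causal form of the band-pass filter (single forward
pass with carried filter state), so the emitted windows are identical to
an offline causal-filtered segmentation of the same samples.
"""

from __future__ import annotations

import json
import time
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .network import ClassifierBase
from .preprocessing import (
    ChannelStats, FilterSpec, FilterMode, RawRecording, WindowSpec,
    design_sos, window_length, _step_samples,
)

__all__ = [
    "VoteBuffer", "StreamReport", "CausalFilter",
    "stream_windows", "majority_vote", "run_stream", "map_command",
    "COMMAND_MAP", "IDLE_COMMAND",
]

#: gesture class -> manipulator command token (six action modes)
COMMAND_MAP = {
    1: "index-finger",
    2: "three-finger-grip",
    3: "thumb-slide",
    4: "thumb-up",
    5: "two-finger-grasp",
    6: "fist",
}
IDLE_COMMAND = "idle"


class VoteBuffer:
    """Fixed-capacity FIFO of recent frame predictions."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("vote window capacity must be >= 1")
        self.capacity = capacity
        self.entries: deque = deque(maxlen=capacity)

    def push(self, label: int) -> None:
        self.entries.append(int(label))

    def __len__(self) -> int:
        return len(self.entries)


def majority_vote(buf: VoteBuffer) -> int:
    """Modal label; ties break toward the most recently observed tied label."""
    if not buf.entries:
        raise ValueError("cannot vote on an empty buffer")
    counts = Counter(buf.entries)
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in reversed(buf.entries):
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


@dataclass
class StreamReport:
    """Everything a streaming run produced, plus informational timing."""

    frame_labels: np.ndarray
    voted_labels: np.ndarray
    commands: List[str]
    window_starts: np.ndarray
    true_labels: Optional[np.ndarray] = None
    mean_response_s: float = float("nan")
    prediction_fps: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.voted_labels) != len(self.frame_labels):
            raise ValueError("voted stream must have one entry per frame")

    def frame_accuracy_pct(self) -> Optional[float]:
        if self.true_labels is None or len(self.frame_labels) == 0:
            return None
        return float(100.0 * np.mean(self.frame_labels == self.true_labels))

    def voted_accuracy_pct(self) -> Optional[float]:
        if self.true_labels is None or len(self.voted_labels) == 0:
            return None
        return float(100.0 * np.mean(self.voted_labels == self.true_labels))

    def to_jsonl(self) -> str:
        lines = []
        for i in range(len(self.frame_labels)):
            lines.append(json.dumps({
                "t": int(self.window_starts[i]),
                "frame_label": int(self.frame_labels[i]),
                "voted_label": int(self.voted_labels[i]),
                "command": self.commands[i],
            }))
        return "\n".join(lines)


class CausalFilter:
    """Streaming band-pass: ``process`` chunks agree exactly with one
    offline causal pass over the concatenated samples."""

    def __init__(self, spec: FilterSpec, f_hz: float, n_channels: int):
        self.sos = design_sos(spec, f_hz)
        zi = sps.sosfilt_zi(self.sos)  # (n_sections, 2)
        self.zi = np.repeat(zi[:, :, np.newaxis], n_channels, axis=2) * 0.0
        self.n_channels = n_channels

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.atleast_2d(np.asarray(chunk, dtype=np.float64))
        out, self.zi = sps.sosfilt(self.sos, chunk, axis=0, zi=self.zi)
        return out


def stream_windows(
    samples: Iterable[np.ndarray],
    wspec: WindowSpec,
    f: float,
    n_channels: Optional[int] = None,
) -> Iterator[Tuple[int, np.ndarray]]:
    """Re-window an ordered sample feed.

    Yields ``(start_index, image)`` pairs where ``image`` is ``L x T x 1``;
    window ``i`` (starting at sample ``i*S``) is emitted as soon as sample
    ``i*S + L - 1`` has arrived. An under-full buffer emits nothing. The
    emitted windows equal an offline segmentation of the same signal.
    """
    it = iter(samples)
    try:
        first = np.atleast_1d(next(it))
    except StopIteration:
        return
    T = len(first) if n_channels is None else n_channels
    L = window_length(wspec.w_ms, f)
    S = _step_samples(wspec.s_ms, f)

    # ring buffer over the last L samples; a window is emitted the moment
    # its final sample arrives
    ring = np.zeros((L, T))
    n_seen = 0
    next_start = 0
    for row in _chain_first(first, it):
        ring[n_seen % L] = row
        n_seen += 1
        while next_start + L <= n_seen:
            idx = np.arange(next_start, next_start + L) % L
            yield next_start, ring[idx][:, :, np.newaxis].copy()
            next_start += S


def _chain_first(first, rest):
    yield first
    for row in rest:
        yield np.atleast_1d(row)


def map_command(label: int) -> str:
    """Fixed bijection from the six gesture classes to command tokens;
    rest (label 0) maps to the idle command."""
    if label == 0:
        return IDLE_COMMAND
    try:
        return COMMAND_MAP[int(label)]
    except KeyError:
        raise ValueError(f"no command mapped for gesture label {label}") from None


def run_stream(
    model: ClassifierBase,
    rec: RawRecording,
    wspec: WindowSpec,
    V: int = 100,
    filter_spec: Optional[FilterSpec] = None,
    stats: Optional[ChannelStats] = None,
    map_commands: bool = True,
) -> StreamReport:
    """Replay a recording as a causal stream: filter, normalise, window,
    predict per frame, majority-vote over the last ``V`` frames.

    ``stats`` should come from the training data (leakage-free). Timing
    numbers (mean response per window, prediction FPS) are measured on
    this machine and reported for information only.
    """
    sig = rec.signal
    if filter_spec is not None:
        cf = CausalFilter(filter_spec, rec.f, rec.n_channels)
        sig = cf.process(sig)
    if stats is not None:
        sig = (sig - stats.mu) / stats.sigma

    L = window_length(wspec.w_ms, rec.f)
    buf = VoteBuffer(V)
    frame_labels: List[int] = []
    voted: List[int] = []
    commands: List[str] = []
    starts: List[int] = []
    true_labels: List[int] = []
    elapsed: List[float] = []

    from .preprocessing import majority_label  # local to avoid cycle at import

    for start, image in stream_windows(iter(sig), wspec, rec.f):
        t0 = time.perf_counter()
        pred = int(model.predict(image[np.newaxis])[0])
        buf.push(pred)
        vote = majority_vote(buf)
        elapsed.append(time.perf_counter() - t0)
        frame_labels.append(pred)
        voted.append(vote)
        commands.append(map_command(vote) if map_commands else str(vote))
        starts.append(start)
        true_labels.append(majority_label(rec.labels[start:start + L]))

    mean_rt = float(np.mean(elapsed)) if elapsed else float("nan")
    fps = float(1.0 / mean_rt) if elapsed and mean_rt > 0 else float("nan")
    return StreamReport(
        frame_labels=np.array(frame_labels, dtype=np.int64),
        voted_labels=np.array(voted, dtype=np.int64),
        commands=commands,
        window_starts=np.array(starts, dtype=np.int64),
        true_labels=np.array(true_labels, dtype=np.int64),
        mean_response_s=mean_rt,
        prediction_fps=fps,
    )
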