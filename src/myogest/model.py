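"""Model/Results facade over the full pipeline.

:class:`GestureClassifier` is built from a raw recording (or an already
windowed dataset) plus the preprocessing and architecture settings;
:meth:`GestureClassifier.fit` runs band-pass filtering, leakage-free
per-channel Z-scoring, windowing, the repetition split and the seeded
training loop, and returns a :class:`GestureFitResults` carrying the
trained network, the held-out evaluation and a ``summary()`` table —
the same shape of API a statsmodels user expects from ``Model.fit()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .network import ClassifierBase, ModelConfig
from .preprocessing import (
    ChannelStats, FilterSpec, RawRecording, WindowSpec, WindowedDataset,
    apply_normalizer, bandpass_filter, fit_normalizer, segment_windows,
)
from .realtime import StreamReport, run_stream
from .training import (
    EvalReport, SplitSpec, TrainConfig, build_ablation, evaluate_model,
    split_by_repetition, train_model,
)

logger = logging.getLogger(__name__)

__all__ = ["GestureClassifier", "GestureFitResults"]


class GestureClassifier:
    """Gesture classifier model specification bound to one recording.

    Parameters
    ----------
    recording : RawRecording
        Continuous labelled multichannel sEMG.
    model_config : ModelConfig, optional
        Architecture constants; ``n_classes`` defaults to the number of
        distinct non-rest labels in the recording.
    filter_spec, window_spec :
        Preprocessing settings (4th-order 10-500 Hz band-pass; 200 ms /
        50 ms windows by default).
    variant : str
        Architecture rung: ``bilstm``, ``attn_cnn``, ``ms_attn_cnn`` or
        ``full``.
    normalizer_scope : str
        ``"train"`` fits the per-channel Z-score statistics on samples
        outside the test repetitions (leakage-free, default); ``"all"``
        uses the whole recording.
    """

    def __init__(
        self,
        recording: RawRecording,
        model_config: Optional[ModelConfig] = None,
        filter_spec: FilterSpec = FilterSpec(),
        window_spec: WindowSpec = WindowSpec(),
        variant: str = "full",
        normalizer_scope: str = "train",
    ):
        if normalizer_scope not in ("train", "all"):
            raise ValueError("normalizer_scope must be 'train' or 'all'")
        self.recording = recording
        self.filter_spec = filter_spec
        self.window_spec = window_spec
        self.variant = variant
        self.normalizer_scope = normalizer_scope
        if model_config is None:
            n_classes = int(recording.labels.max())
            model_config = ModelConfig(n_classes=n_classes)
        self.model_config = model_config

    @classmethod
    def from_dataframe(cls, df, f: float, subject_id: str = "S?", **kwargs) -> "GestureClassifier":
        """Build from a ``ch1..chT, label, repetition`` DataFrame."""
        chan_cols = sorted((c for c in df.columns if c.startswith("ch")),
                           key=lambda c: int(c[2:]))
        rec = RawRecording(df[chan_cols].to_numpy(), f,
                           df["label"].to_numpy(), df["repetition"].to_numpy(),
                           subject_id)
        return cls(rec, **kwargs)

    # ------------------------------------------------------------------

    def prepare(self, split: SplitSpec):
        """Filter, normalise and window the recording; return
        (train, test, stats)."""
        filtered = bandpass_filter(self.recording, self.filter_spec)
        if self.normalizer_scope == "train":
            fit_mask = ~np.isin(filtered.repetitions, list(split.test_reps))
            fit_rec = RawRecording(filtered.signal[fit_mask], filtered.f,
                                   filtered.labels[fit_mask],
                                   filtered.repetitions[fit_mask],
                                   filtered.subject_id)
        else:
            fit_rec = filtered
        stats = fit_normalizer(fit_rec)
        normalized = apply_normalizer(filtered, stats)
        windows = segment_windows(normalized, self.window_spec)
        train, test = split_by_repetition(windows, split)
        return train, test, stats

    def fit(
        self,
        split: SplitSpec = SplitSpec({1, 3, 4, 6}, {2, 5}),
        train_config: Optional[TrainConfig] = None,
    ) -> "GestureFitResults":
        """Run the full pipeline and training loop; returns the results object."""
        cfg = train_config or TrainConfig(variant=self.variant)
        if cfg.variant != self.variant:
            cfg = TrainConfig(optimizer=cfg.optimizer, lr=cfg.lr,
                              batch_size=cfg.batch_size, epochs=cfg.epochs,
                              seed=cfg.seed, variant=self.variant)
        train, test, stats = self.prepare(split)
        logger.info("fit: %d train / %d test windows of shape %s",
                    len(train), len(test), train.image_shape)
        net = build_ablation(self.variant, self.model_config, self.recording.n_channels)
        net, loss_history = train_model(net, train, cfg)
        report = evaluate_model(net, test, loss_history)
        return GestureFitResults(self, net, stats, report, split, cfg,
                                 n_train=len(train), n_test=len(test))


@dataclass
class GestureFitResults:
    """Trained network plus everything needed to evaluate and deploy it."""

    model: GestureClassifier
    network: ClassifierBase
    stats: ChannelStats
    report: EvalReport
    split: SplitSpec
    train_config: TrainConfig
    n_train: int
    n_test: int

    @property
    def accuracy_pct(self) -> float:
        return self.report.accuracy_pct

    @property
    def loss_history(self) -> List[float]:
        return self.report.loss_history

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict(images)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(images)

    def stream(self, recording: RawRecording, vote_window: int = 100,
               **kwargs) -> StreamReport:
        """Causal streaming inference on a new recording with this fit's
        normaliser and the causal form of its band-pass filter."""
        from .preprocessing import FilterMode, FilterSpec as FS
        fspec = self.model.filter_spec
        causal = FS(fspec.order, fspec.low_hz, fspec.high_hz, FilterMode.causal_streaming)
        return run_stream(self.network, recording, self.model.window_spec,
                          V=vote_window, filter_spec=causal, stats=self.stats,
                          **kwargs)

    def save(self, path) -> None:
        from .io import save_checkpoint
        save_checkpoint(path, self.network, self.train_config.variant, self.stats,
                        extra={"n_channels": self.model.recording.n_channels})

    def summary(self) -> str:
        r = self.report
        lines = [
            "Gesture classification fit",
            "==========================",
            f"subject:            {self.model.recording.subject_id}",
            f"variant:            {self.train_config.variant}",
            f"classes:            {self.model.model_config.n_classes}",
            f"parameters:         {self.network.n_parameters():,}",
            f"window / step:      {self.model.window_spec.w_ms:g} ms / "
            f"{self.model.window_spec.s_ms:g} ms at {self.model.recording.f:g} Hz",
            f"train repetitions:  {sorted(self.split.train_reps)}  ({self.n_train} windows)",
            f"test repetitions:   {sorted(self.split.test_reps)}  ({self.n_test} windows)",
            f"epochs:             {self.train_config.epochs} "
            f"(final loss {r.loss_history[-1]:.4f})" if r.loss_history else
            f"epochs:             {self.train_config.epochs}",
            f"held-out accuracy:  {r.accuracy_pct:.2f} %",
            "",
            "confusion matrix (rows = true class):",
            r.confusion_text(),
        ]
        return "\n".join(lines)
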