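"""Repetition-based splitting, metrics, and the seeded training loop.

Evaluation follows standard practice for gesture datasets: whole
repetitions are held out (e.g. repetitions {1, 3, 4, 6} train and {2, 5}
test on a six-repetition protocol), so no window from a test repetition
ever influences training. Accuracy is the percentage of correctly
classified test windows; the average accuracy over subjects is their
arithmetic mean. The loss is the mean categorical cross-entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, Tensor
from .network import (
    AttentionCNNClassifier, ClassifierBase, ModelConfig, MultiScaleAttentionCNN,
    MultiScaleConvLSTM, StackedBiLSTMClassifier,
)
from .preprocessing import WindowedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec", "TrainConfig", "EvalReport", "ABLATION_VARIANTS",
    "split_by_repetition", "cross_entropy_loss", "accuracy",
    "average_accuracy", "confusion_matrix", "train_model", "build_ablation",
    "evaluate_model",
]

#: probability floor keeping the cross-entropy finite
PROB_CLAMP = 1e-12

#: ablation ladder, weakest to full model
ABLATION_VARIANTS = ("bilstm", "attn_cnn", "ms_attn_cnn", "full")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint repetition sets for training and testing."""

    train_reps: frozenset
    test_reps: frozenset

    def __init__(self, train_reps: Iterable[int], test_reps: Iterable[int]):
        tr, te = frozenset(train_reps), frozenset(test_reps)
        if not tr or not te:
            raise ValueError("train and test repetition sets must be non-empty")
        if tr & te:
            raise ValueError(f"repetition sets overlap: {sorted(tr & te)}")
        object.__setattr__(self, "train_reps", tr)
        object.__setattr__(self, "test_reps", te)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings. Adam throughout; defaults suit the synthetic
    smoke datasets (they are not stated by any benchmark protocol)."""

    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {ABLATION_VARIANTS}")


@dataclass
class EvalReport:
    """Per-subject accuracy, confusion matrix, and the training-loss trace."""

    accuracy_pct: float
    confusion: np.ndarray
    loss_history: List[float] = field(default_factory=list)
    subject_id: str = "S?"

    def to_dict(self) -> Dict:
        return {
            "subject_id": self.subject_id,
            "accuracy_pct": self.accuracy_pct,
            "confusion": self.confusion.tolist(),
            "loss_history": list(self.loss_history),
        }

    def confusion_text(self) -> str:
        m = self.confusion
        classes = range(1, m.shape[0] + 1)
        header = "true\\pred " + " ".join(f"{c:>6d}" for c in classes)
        rows = [header]
        for c, row in zip(classes, m):
            rows.append(f"{c:>9d} " + " ".join(f"{v:>6d}" for v in row))
        return "\n".join(rows)


def split_by_repetition(ds: WindowedDataset, spec: SplitSpec) -> Tuple[WindowedDataset, WindowedDataset]:
    """Partition windows by repetition id; windows outside both sets are dropped."""
    reps = ds.repetitions
    train_mask = np.isin(reps, list(spec.train_reps))
    test_mask = np.isin(reps, list(spec.test_reps))
    train, test = ds.subset(train_mask), ds.subset(test_mask)
    if len(train) == 0 or len(test) == 0:
        raise ValueError(
            f"empty partition: {len(train)} train / {len(test)} test windows "
            f"for reps {sorted(spec.train_reps)} / {sorted(spec.test_reps)}"
        )
    return train, test


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, ``(1/S) sum_i -log p_i[c_i]``.

    ``probs`` rows are class probability vectors; ``labels`` are 1-based
    class ids. Probabilities are clamped at 1e-12 to stay finite.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or len(labels) != probs.shape[0]:
        raise ValueError("probs must be (S, M) with one label per row")
    if labels.min() < 1 or labels.max() > probs.shape[1]:
        raise ValueError("labels must lie in 1..M")
    p = np.clip(probs[np.arange(len(labels)), labels - 1], PROB_CLAMP, None)
    return float(-np.mean(np.log(p)))


def accuracy(preds: np.ndarray, labels: np.ndarray) -> float:
    """Percentage of correct predictions: 100 x #correct / #total."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape or preds.size == 0:
        raise ValueError("preds and labels must be equal-length, non-empty")
    return float(100.0 * np.mean(preds == labels))


def average_accuracy(per_subject: Sequence[float]) -> float:
    """Arithmetic mean of per-subject accuracies (percent)."""
    per_subject = list(per_subject)
    if not per_subject:
        raise ValueError("need at least one subject accuracy")
    return float(np.mean(per_subject))


def confusion_matrix(preds: np.ndarray, labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Row = true class (1..M), column = predicted class."""
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(labels, preds):
        m[t - 1, p - 1] += 1
    return m


def build_ablation(variant: str, cfg: ModelConfig, n_channels: int) -> ClassifierBase:
    """Instantiate one rung of the ablation ladder.

    ``bilstm``      three stacked Bi-LSTM layers on the raw window rows
    ``attn_cnn``    plain conv stem + residual block attention
    ``ms_attn_cnn`` multi-scale block + residual block attention
    ``full``        the complete multi-scale conv + Bi-LSTM network
    """
    if variant == "bilstm":
        return StackedBiLSTMClassifier(cfg, n_channels)
    if variant == "attn_cnn":
        return AttentionCNNClassifier(cfg)
    if variant == "ms_attn_cnn":
        return MultiScaleAttentionCNN(cfg)
    if variant == "full":
        return MultiScaleConvLSTM(cfg)
    raise ValueError(f"unknown ablation variant {variant!r}")


def train_model(
    model: ClassifierBase,
    train: WindowedDataset,
    cfg: TrainConfig,
) -> Tuple[ClassifierBase, List[float]]:
    """Seeded mini-batch Adam training; returns the model and per-epoch mean loss.

    Window labels are 1-based class ids; the model's output unit ``c-1``
    corresponds to class ``c``. Aborts on non-finite loss.
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    images, labels = train.images, train.labels
    n = len(train)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng([cfg.seed, 2])
    model.train()
    loss_history: List[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            x = Tensor(images[idx])
            y = labels[idx] - 1
            logits = model.forward_logits(x)
            logp = logits.log_softmax(axis=1)
            loss = -(logp[np.arange(len(idx)), y].mean())
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        loss_history.append(epoch_loss / n)
        logger.info("epoch %d/%d: mean loss %.4f", epoch + 1, cfg.epochs, loss_history[-1])
    model.eval()
    return model, loss_history


def evaluate_model(
    model: ClassifierBase,
    test: WindowedDataset,
    loss_history: Optional[List[float]] = None,
) -> EvalReport:
    """Held-out accuracy and confusion matrix on a windowed test set."""
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    preds = model.predict(test.images)
    acc = accuracy(preds, test.labels)
    conf = confusion_matrix(preds, test.labels, model.cfg.n_classes)
    return EvalReport(
        accuracy_pct=acc,
        confusion=conf,
        loss_history=list(loss_history or []),
        subject_id=test.subject_id,
    )
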