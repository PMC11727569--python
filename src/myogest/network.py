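"""Two-branch multi-scale convolutional network with residual block
attention and a bidirectional LSTM head for sEMG window images.

The input is an ``L x T x 1`` window image (time x electrode x feature
channel). Two parallel branches process it at different receptive-field
scales: each branch is a four-way multi-scale (Inception-style) block —
two time-axis kernels, one electrode-axis kernel, and a max-pooled branch
— concatenated to 32 feature channels, followed by a residual unit wrapped
in convolutional block attention (channel attention, then spatial
attention with a 2x2 kernel). The two branches are pooled over the
electrode axis, downsampled to ``tau`` time steps, and fused into 128-dim
step vectors; a single bidirectional LSTM (hidden 128 per direction)
summarises the sequence into a 256-dim vector that feeds the softmax
classifier through dropout.

Architecture constants (the small branch's 5x1 / 8x1 / 1x2 kernels, the
big branch's 10x1 / 20x1 / 1x4, the 2x2 pooling and attention kernels,
8 kernels per branch arm, the 128-dim fused features and 256-dim
recurrent output) are carried in :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .nn import (
    Tensor, concat, conv2d, maxpool2d, no_grad,
    Module, Conv2d, Linear, BatchNorm2d, Dropout, BiLSTM,
)

__all__ = [
    "ScaleParams", "ModelConfig",
    "MultiScaleBlock", "ChannelAttention", "SpatialAttention", "ResidualCBAM",
    "TemporalFuse", "ClassifierBase", "MultiScaleConvLSTM",
    "StackedBiLSTMClassifier", "AttentionCNNClassifier", "MultiScaleAttentionCNN",
    "SMALL_SCALE", "BIG_SCALE",
]


@dataclass(frozen=True)
class ScaleParams:
    """Kernel extents of one multi-scale branch (time_a x1, time_b x1, 1x chan)."""

    k_time_a: int
    k_time_b: int
    k_chan: int
    pool: Tuple[int, int] = (2, 2)
    n_kernels: int = 8

    def __post_init__(self) -> None:
        if min(self.k_time_a, self.k_time_b, self.k_chan, self.n_kernels) < 1:
            raise ValueError("kernel extents and kernel count must be >= 1")


SMALL_SCALE = ScaleParams(k_time_a=5, k_time_b=8, k_chan=2)
BIG_SCALE = ScaleParams(k_time_a=10, k_time_b=20, k_chan=4)


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture constant, plus the choices the design left open."""

    n_classes: int = 6
    small: ScaleParams = SMALL_SCALE
    big: ScaleParams = BIG_SCALE
    attn_spatial_a: int = 2
    attn_reduction_r: int = 8
    fused_dim: int = 128
    rnn_hidden: int = 128
    tau: int = 8
    dropout_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.tau < 1 or self.fused_dim < 1 or self.rnn_hidden < 1:
            raise ValueError("tau, fused_dim, rnn_hidden must be >= 1")

    @property
    def ms_out_channels(self) -> int:
        return 4 * self.small.n_kernels  # four branches concatenated

    def to_dict(self) -> Dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelConfig":
        d = dict(d)
        for key in ("small", "big"):
            if key in d and isinstance(d[key], dict):
                sp = dict(d[key])
                if "pool" in sp:
                    sp["pool"] = tuple(sp["pool"])
                d[key] = ScaleParams(**sp)
        return cls(**d)


class MultiScaleBlock(Module):
    """Four-branch Inception-style block; every branch emits ``n_kernels``
    feature channels at the input spatial size, concatenated to 4x that.

    Branches: conv ``k_time_a x 1`` and ``k_time_b x 1`` along the time
    axis, conv ``1 x k_chan`` along the electrode axis, and a 2x2
    stride-1 max-pool followed by a 1x1 conv that lifts the pooled map to
    the same feature-channel count as the other branches.
    """

    def __init__(self, cin: int, p: ScaleParams, rng: np.random.Generator):
        super().__init__()
        k = p.n_kernels
        self.conv_time_a = Conv2d(cin, k, (p.k_time_a, 1), rng)
        self.conv_time_b = Conv2d(cin, k, (p.k_time_b, 1), rng)
        self.conv_chan = Conv2d(cin, k, (1, p.k_chan), rng)
        self.pool_k = p.pool
        self.conv_pool = Conv2d(cin, k, (1, 1), rng)
        self.min_extent = (max(p.k_time_a, p.k_time_b), p.k_chan)

    def forward(self, x: Tensor) -> Tensor:
        L, T = x.shape[1], x.shape[2]
        if L < self.min_extent[0] or T < self.min_extent[1]:
            raise ValueError(
                f"window image {L}x{T} smaller than the largest kernel {self.min_extent}"
            )
        b1 = self.conv_time_a(x).relu()
        b2 = self.conv_time_b(x).relu()
        b3 = self.conv_chan(x).relu()
        b4 = self.conv_pool(maxpool2d(x, self.pool_k)).relu()
        return concat([b1, b2, b3, b4], axis=3)


class ChannelAttention(Module):
    """CBAM channel attention: spatially average- and max-pooled descriptors
    through a shared two-layer bottleneck (C -> C/r -> C), summed, sigmoid."""

    def __init__(self, c: int, r: int, rng: np.random.Generator):
        super().__init__()
        if c < r or c % r != 0:
            raise ValueError(f"feature channels ({c}) must be divisible by reduction r={r}")
        self.fc1 = Linear(c, c // r, rng)
        self.fc2 = Linear(c // r, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Returns the (B, C) channel weight map in (0, 1)."""
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=1).max(axis=1)
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()


class SpatialAttention(Module):
    """CBAM spatial attention with an ``a x a`` kernel (default 2x2).

    Per-position average and max over the feature channels give a
    2-channel map; one size-preserving convolution (the even 2x2 kernel
    pads one extra row/column on the bottom/right) and a sigmoid produce
    the (B, L, T) spatial map.
    """

    def __init__(self, a: int, rng: np.random.Generator):
        super().__init__()
        if a < 1:
            raise ValueError("attention kernel extent must be >= 1")
        self.conv = Conv2d(2, 1, (a, a), rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=3, keepdims=True)
        mx = x.max(axis=3, keepdims=True)
        m = self.conv(concat([avg, mx], axis=3))
        return m.sigmoid()  # (B, L, T, 1)


class _ResidualUnit(Module):
    """conv 3x1 -> BN -> ReLU -> conv 3x1 -> BN (identity shortcut added by caller)."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c, c, (3, 1), rng)
        self.bn1 = BatchNorm2d(c)
        self.conv2 = Conv2d(c, c, (3, 1), rng)
        self.bn2 = BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))


class ResidualCBAM(Module):
    """Attention first, then a shallow residual refinement.

    ``y = x * channel_weights * spatial_map``; output
    ``ReLU(y + ResidualUnit(y))`` — the shortcut keeps the attended
    features intact, which matters on small, sparse sEMG datasets.
    """

    def __init__(self, c: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.channel_attn = ChannelAttention(c, cfg.attn_reduction_r, rng)
        self.spatial_attn = SpatialAttention(cfg.attn_spatial_a, rng)
        self.residual = _ResidualUnit(c, rng)

    def apply_attention(self, x: Tensor) -> Tensor:
        cw = self.channel_attn(x)
        B, C = cw.shape
        y = x * cw.reshape(B, 1, 1, C)
        return y * self.spatial_attn(y)

    def forward(self, x: Tensor) -> Tensor:
        y = self.apply_attention(x)
        return (y + self.residual(y)).relu()


class TemporalFuse(Module):
    """Fuse the two branches into ``tau`` steps of ``fused_dim`` features.

    Each branch map (B, L, T, C) is averaged over the electrode axis,
    adaptively average-pooled along time to ``tau`` steps, concatenated
    across branches, and linearly projected to ``fused_dim`` per step.
    """

    def __init__(self, c_per_branch: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.tau = cfg.tau
        self.fused_dim = cfg.fused_dim
        self.project = Linear(2 * c_per_branch, cfg.fused_dim, rng)

    def _pool_branch(self, x: Tensor) -> Tensor:
        B, L, T, C = x.shape
        if L < self.tau:
            raise ValueError(f"time extent {L} shorter than tau={self.tau}")
        z = x.mean(axis=2)  # (B, L, C)
        bounds = [round(i * L / self.tau) for i in range(self.tau + 1)]
        steps = [z[:, a:b, :].mean(axis=1, keepdims=True) for a, b in zip(bounds, bounds[1:])]
        return concat(steps, axis=1)  # (B, tau, C)

    def forward(self, small: Tensor, big: Tensor) -> Tensor:
        if small.shape[1] != big.shape[1]:
            raise ValueError("branch time extents differ")
        z = concat([self._pool_branch(small), self._pool_branch(big)], axis=2)
        B, tau, C2 = z.shape
        out = self.project(z.reshape(B * tau, C2))
        return out.reshape(B, tau, self.fused_dim)


class ClassifierBase(Module):
    """Shared prediction surface for all architecture variants."""

    cfg: ModelConfig

    def forward_logits(self, x: Tensor, intermediates: Optional[Dict] = None) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class probabilities for a stack of (N, L, T, 1) images (eval mode)."""
        was_training = self.training
        self.eval()
        out = []
        with no_grad():
            for i in range(0, len(images), batch_size):
                logits = self.forward_logits(Tensor(images[i:i + batch_size]))
                out.append(np.exp(logits.log_softmax(axis=1).data))
        if was_training:
            self.train()
        return np.concatenate(out, axis=0) if out else np.empty((0, self.cfg.n_classes))

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Predicted class ids (1-based, matching window labels)."""
        return self.predict_proba(images, batch_size).argmax(axis=1) + 1


class MultiScaleConvLSTM(ClassifierBase):
    """The full classifier: two scale branches -> temporal fusion -> Bi-LSTM
    -> dropout -> dense -> softmax."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.ms_out_channels
        self.ms_small = MultiScaleBlock(1, cfg.small, rng)
        self.ms_big = MultiScaleBlock(1, cfg.big, rng)
        self.rescbam_small = ResidualCBAM(c, cfg, rng)
        self.rescbam_big = ResidualCBAM(c, cfg, rng)
        self.fuse = TemporalFuse(c, cfg, rng)
        self.bilstm = BiLSTM(cfg.fused_dim, cfg.rnn_hidden, rng)
        self.dropout = Dropout(cfg.dropout_p, np.random.default_rng([cfg.seed, 1]))
        self.classifier = Linear(2 * cfg.rnn_hidden, cfg.n_classes, rng)

    def forward_logits(self, x: Tensor, intermediates: Optional[Dict] = None) -> Tensor:
        """x: (B, L, T, 1) window images -> (B, n_classes) logits."""
        small = self.rescbam_small(self.ms_small(x))
        big = self.rescbam_big(self.ms_big(x))
        fused = self.fuse(small, big)           # (B, tau, 128)
        _, feat = self.bilstm(fused)            # (B, 256)
        if intermediates is not None:
            intermediates["fused"] = fused
            intermediates["recurrent"] = feat
        return self.classifier(self.dropout(feat))

    forward = forward_logits


class StackedBiLSTMClassifier(ClassifierBase):
    """Pure recurrent baseline: three stacked Bi-LSTM layers reading the raw
    window rows (one electrode vector per time sample); no convolutions."""

    def __init__(self, cfg: ModelConfig, n_channels: int):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        H = cfg.rnn_hidden
        self.layers = [
            BiLSTM(n_channels, H, rng),
            BiLSTM(2 * H, H, rng),
            BiLSTM(2 * H, H, rng),
        ]
        self.dropout = Dropout(cfg.dropout_p, np.random.default_rng([cfg.seed, 1]))
        self.classifier = Linear(2 * H, cfg.n_classes, rng)

    def forward_logits(self, x: Tensor, intermediates: Optional[Dict] = None) -> Tensor:
        B, L, T, C = x.shape
        seq = x.reshape(B, L, T * C)
        final = None
        for layer in self.layers:
            seq, final = layer(seq)
        return self.classifier(self.dropout(final))

    forward = forward_logits


class AttentionCNNClassifier(ClassifierBase):
    """Residual-attention CNN without the multi-scale block: a plain 3x3 conv
    stem lifts the image to 32 feature channels so the attention block's
    input contract holds, then global average pooling feeds the classifier."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.ms_out_channels
        self.stem = Conv2d(1, c, (3, 3), rng)
        self.rescbam = ResidualCBAM(c, cfg, rng)
        self.dropout = Dropout(cfg.dropout_p, np.random.default_rng([cfg.seed, 1]))
        self.classifier = Linear(c, cfg.n_classes, rng)

    def forward_logits(self, x: Tensor, intermediates: Optional[Dict] = None) -> Tensor:
        h = self.rescbam(self.stem(x).relu())
        pooled = h.mean(axis=(1, 2))  # (B, C)
        return self.classifier(self.dropout(pooled))

    forward = forward_logits


class MultiScaleAttentionCNN(ClassifierBase):
    """Multi-scale block + residual attention, no recurrent head: the fused
    tau x 128 step sequence is averaged over time and classified directly."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.ms_out_channels
        self.ms_small = MultiScaleBlock(1, cfg.small, rng)
        self.ms_big = MultiScaleBlock(1, cfg.big, rng)
        self.rescbam_small = ResidualCBAM(c, cfg, rng)
        self.rescbam_big = ResidualCBAM(c, cfg, rng)
        self.fuse = TemporalFuse(c, cfg, rng)
        self.dropout = Dropout(cfg.dropout_p, np.random.default_rng([cfg.seed, 1]))
        self.classifier = Linear(cfg.fused_dim, cfg.n_classes, rng)

    def forward_logits(self, x: Tensor, intermediates: Optional[Dict] = None) -> Tensor:
        small = self.rescbam_small(self.ms_small(x))
        big = self.rescbam_big(self.ms_big(x))
        fused = self.fuse(small, big)
        if intermediates is not None:
            intermediates["fused"] = fused
        return self.classifier(self.dropout(fused.mean(axis=1)))

    forward = forward_logits
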