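"""Neural-network building blocks on top of the autodiff tensor.

Weight initialisation is fan-in-scaled uniform (the Kaiming/LeCun family)
drawn from a ``numpy.random.Generator`` supplied by the caller, so a model
is fully determined by its seed.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .tensor import Tensor, concat, conv2d, maxpool2d, same_padding

__all__ = [
    "Module", "Parameter", "Conv2d", "Linear", "BatchNorm2d",
    "Dropout", "BiLSTM", "Sequential",
]


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _uniform_fan_in(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Tiny module system: parameter discovery and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def _modules(self) -> Iterable["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # state serialisation -------------------------------------------------

    def state_arrays(self) -> List[np.ndarray]:
        """All learnable and buffer arrays in a stable traversal order."""
        arrays: List[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                arrays.append(v.data)
            elif isinstance(v, np.ndarray):  # buffers (batch-norm running stats)
                arrays.append(v)
            elif isinstance(v, Module):
                arrays.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        self._load(it)
        try:
            next(it)
        except StopIteration:
            return
        raise ValueError("too many arrays for this module's state")

    def _load(self, it) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                arr = np.asarray(next(it))
                if arr.shape != v.data.shape:
                    raise ValueError(f"shape mismatch loading {k}: {arr.shape} vs {v.data.shape}")
                v.data = arr.astype(np.float64)
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(next(it), dtype=np.float64)
            elif isinstance(v, Module):
                v._load(it)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._load(it)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 same-padded convolution, NHWC, kernel (kh, kw, Cin, Cout)."""

    def __init__(self, cin: int, cout: int, kernel: Tuple[int, int],
                 rng: np.random.Generator, pad=None):
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * cin
        self.weight = Parameter(_uniform_fan_in(rng, (kh, kw, cin, cout), fan_in))
        self.bias = Parameter(np.zeros(cout))
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_uniform_fan_in(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (batch, H, W) for each feature channel."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 1, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * Tensor((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask RNG is supplied once."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * Tensor(mask)


class _LSTMDirection(Module):
    """One direction of an LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Parameter(_uniform_fan_in(rng, (n_in, 4 * hidden), n_in))
        self.wh = Parameter(_uniform_fan_in(rng, (hidden, 4 * hidden), hidden))
        self.bias = Parameter(np.zeros(4 * hidden))

    def forward(self, x: Tensor, reverse: bool = False):
        """x: (B, tau, n_in) -> list of tau hidden states (B, H), in input order."""
        B, tau, n_in = x.shape
        H = self.hidden
        # all input projections in one matmul
        xw = (x.reshape(B * tau, n_in) @ self.wx + self.bias).reshape(B, tau, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(tau - 1, -1, -1) if reverse else range(tau)
        outputs: List[Optional[Tensor]] = [None] * tau
        for t in steps:
            z = xw[:, t, :] + h @ self.wh
            i = z[:, 0:H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return outputs, h


class BiLSTM(Module):
    """Bidirectional LSTM layer over (B, tau, n_in) sequences.

    ``forward`` returns the per-step output sequence (B, tau, 2H) and the
    concatenation of the two directions' final hidden states (B, 2H).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)

    def forward(self, x: Tensor):
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        out_f, last_f = self.fwd(x, reverse=False)
        out_b, last_b = self.bwd(x, reverse=True)
        steps = [concat([f.reshape(f.shape[0], 1, f.shape[1]),
                         b.reshape(b.shape[0], 1, b.shape[1])], axis=2)
                 for f, b in zip(out_f, out_b)]
        seq = concat(steps, axis=1)
        final = concat([last_f, last_b], axis=1)
        return seq, final


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
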