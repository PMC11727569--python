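"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; :meth:`Tensor.backward` runs a topological sweep accumulating
gradients. The op set is exactly what the gesture-recognition network
needs: broadcast arithmetic, matmul, the usual pointwise nonlinearities,
axis reductions, shape surgery, stride-1 same-padded 2-D convolution and
max-pooling (im2col under the hood), and a numerically stable
log-softmax for the cross-entropy loss.

Convolutions use the NHWC layout throughout: (batch, time, electrode,
feature-channel), matching the L x T x C window-image convention.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "stack", "conv2d", "maxpool2d", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph plumbing -------------------------------------------------

    @classmethod
    def _make(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo = _toposort(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in topo:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior nodes never expose their gradient; freeing it
                # keeps long recurrent graphs within memory
                if node._parents:
                    node.grad = None

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other) -> "Tensor":
        return (-self) + other

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        assert self.data.ndim == 2 and other.data.ndim == 2, "matmul is 2-D only"

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data  # ties share the gradient
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg / counts)

        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(res, (self,), backward)

    # -- shape surgery ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(i, (np.ndarray, list)) for i in parts)

        def backward(g):
            if self.requires_grad:
                # accumulate straight into the slice: allocating a dense
                # zeros array per slice would blow up long recurrent graphs
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if fancy:
                    np.add.at(self.grad, idx, g)
                else:
                    self.grad[idx] += g

        return Tensor._make(self.data[idx], (self,), backward)

    # -- losses ----------------------------------------------------------

    def log_softmax(self, axis: int = 1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        s = self.data - m
        lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
        out_data = s - lse
        softmax = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)


def _toposort(root: Tensor) -> List[Tensor]:
    """Reverse topological order of the grad-requiring subgraph."""
    order: List[Tensor] = []
    seen = set()
    stack: List[Tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order[::-1]


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.data.shape)
        shape.insert(axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


PadPair = Tuple[int, int]


def same_padding(k: int) -> PadPair:
    """Stride-1 'same' padding; even kernels pad one extra on the trailing side."""
    total = k - 1
    lead = total // 2
    return (lead, total - lead)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           pad: Optional[Tuple[PadPair, PadPair]] = None) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NHWC x (kh, kw, Cin, Cout).

    Default padding preserves the spatial size; even kernel extents pad
    the trailing (bottom/right) side one extra, so e.g. a 2x2 kernel maps
    L x T to L x T.
    """
    kh, kw, cin, cout = w.data.shape
    if x.data.shape[3] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[3]} channels, kernel expects {cin}")
    if pad is None:
        pad = (same_padding(kh), same_padding(kw))
    xp = np.pad(x.data, ((0, 0), pad[0], pad[1], (0, 0)))
    B, Hp, Wp, _ = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d: spatial dims {x.data.shape[1:3]} smaller than kernel {(kh, kw)}")
    # (B, Ho, Wo, Cin, kh, kw) -> (B*Ho*Wo, kh*kw*Cin)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * Ho * Wo, kh * kw * cin)
    wflat = w.data.reshape(kh * kw * cin, cout)
    out_data = (cols @ wflat).reshape(B, Ho, Wo, cout)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gflat = g.reshape(B * Ho * Wo, cout)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            w._accum((cols.T @ gflat).reshape(kh, kw, cin, cout))
        if x.requires_grad:
            gcols = (gflat @ wflat.T).reshape(B, Ho, Wo, kh, kw, cin)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + Ho, j:j + Wo, :] += gcols[:, :, :, i, j, :]
            h0, w0 = pad[0][0], pad[1][0]
            x._accum(gxp[:, h0:h0 + x.data.shape[1], w0:w0 + x.data.shape[2], :])

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, k: Tuple[int, int] = (2, 2),
              pad: Optional[Tuple[PadPair, PadPair]] = None) -> Tensor:
    """Stride-1 same-size max pooling over (kh, kw) neighbourhoods, NHWC."""
    kh, kw = k
    if pad is None:
        pad = (same_padding(kh), same_padding(kw))
    xp = np.pad(x.data, ((0, 0), pad[0], pad[1], (0, 0)), constant_values=-np.inf)
    B, Hp, Wp, C = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (B,Ho,Wo,C,kh,kw)
    flat = win.reshape(B, Ho, Wo, C, kh * kw)
    idx = flat.argmax(axis=4)
    out_data = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((B, Hp, Wp, C))
        for kk in range(kh * kw):
            i, j = divmod(kk, kw)
            mask = idx == kk
            gxp[:, i:i + Ho, j:j + Wo, :] += g * mask
        h0, w0 = pad[0][0], pad[1][0]
        x._accum(gxp[:, h0:h0 + x.data.shape[1], w0:w0 + x.data.shape[2], :])

    return Tensor._make(out_data, (x,), backward)
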