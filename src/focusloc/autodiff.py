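"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks on a single CPU; the
engine below provides exactly the primitives those networks need
(elementwise arithmetic, matmul, strided 1-D convolution, reductions,
indexing, concatenation, the activation/loss heads, and a gradient
reversal hook for adversarial training) with reverse-mode gradients.

Tensors wrap ``float64`` numpy arrays.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward`, which topologically sorts
the recorded tape.  A module-level switch (:func:`no_grad`) disables
tape recording for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables gradient tape recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[], None]] = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # release the tape eagerly: every consumer of this node has
            # already run, so intermediate grads and edges can go
            if node._parents:
                node.grad = None
                node._backward = None
                node._parents = ()

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    # convenience wrappers
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out.requires_grad = req
    out._parents = tuple(parents) if req else ()
    out._backward = backward if req else None
    return out


# ----------------------------------------------------------------------
# primitive ops
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data
    out = _make(data, (a, b), None)

    def _bw():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data
    out = _make(data, (a, b), None)

    def _bw():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def power(a, p) -> Tensor:
    a = _as_tensor(a)
    if isinstance(p, Tensor):
        raise TypeError("tensor exponents are not supported")
    data = a.data ** p
    out = _make(data, (a,), None)

    def _bw():
        a._accum(_unbroadcast(out.grad * p * a.data ** (p - 1), a.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)
    out = _make(data, (a,), None)

    def _bw():
        a._accum(out.grad * data)

    out._backward = _bw if out.requires_grad else None
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)
    out = _make(data, (a,), None)

    def _bw():
        a._accum(out.grad / a.data)

    out._backward = _bw if out.requires_grad else None
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data
    out = _make(data, (a, b), None)

    def _bw():
        g = out.grad
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    out = _make(np.asarray(data), (a,), None)

    def _bw():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    out._backward = _bw if out.requires_grad else None
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)
    out = _make(data, (a,), None)

    def _bw():
        a._accum(out.grad.reshape(a.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    out = _make(data, (a,), None)

    def _bw():
        if axes is None:
            a._accum(out.grad.transpose())
        else:
            inv = np.argsort(axes)
            a._accum(out.grad.transpose(inv))

    out._backward = _bw if out.requires_grad else None
    return out


def take(a, idx) -> Tensor:
    """Indexing/slicing; gradients scatter-add back into the source."""
    a = _as_tensor(a)
    data = a.data[idx]
    out = _make(np.asarray(data), (a,), None)

    def _bw():
        g = np.zeros_like(a.data)
        np.add.at(g, idx, out.grad)
        a._accum(g)

    out._backward = _bw if out.requires_grad else None
    return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    out = _make(data, ts, None)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * data.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(out.grad[tuple(sl)])

    out._backward = _bw if out.requires_grad else None
    return out


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg = np.minimum(a.data, 0.0)
    data = np.where(a.data > 0, a.data, alpha * np.expm1(neg))
    out = _make(data, (a,), None)

    def _bw():
        deriv = np.where(a.data > 0, 1.0, alpha * np.exp(neg))
        a._accum(out.grad * deriv)

    out._backward = _bw if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(data, (a,), None)

    def _bw():
        a._accum(out.grad * data * (1.0 - data))

    out._backward = _bw if out.requires_grad else None
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = _make(p, (a,), None)

    def _bw():
        g = out.grad
        dot = (g * p).sum(axis=axis, keepdims=True)
        a._accum(p * (g - dot))

    out._backward = _bw if out.requires_grad else None
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax(``logits``).

    ``class_weights[c]`` scales the loss contribution of samples whose
    true class is ``c`` (used for the imbalance-weighted loss); the mean
    over the batch is unnormalised (plain 1/N), matching the form
    ``-(1/N) sum_i w_{y_i} log p_{i,y_i}``.
    """
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    w = np.ones(n) if class_weights is None else np.asarray(class_weights, float)[labels]
    eps = 1e-12
    losses = -w * np.log(np.maximum(p[np.arange(n), labels], eps))
    out = _make(np.asarray(losses.mean()), (logits,), None)

    def _bw():
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels] = 1.0
        glog = (p - onehot) * w[:, None] / n
        logits._accum(out.grad * glog)

    out._backward = _bw if out.requires_grad else None
    return out


def grad_reverse(a: Tensor, lam: float = 1.0) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by ``-lam``."""
    a = _as_tensor(a)
    out = _make(a.data, (a,), None)

    def _bw():
        a._accum(-lam * out.grad)

    out._backward = _bw if out.requires_grad else None
    return out


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding=(0, 0)) -> Tensor:
    """Strided cross-correlation of a batch of 1-D multichannel signals.

    ``x`` has shape (N, C, W); ``w`` has shape (O, C, R).  ``padding``
    is a (left, right) pair of zero-padding widths.  Output is
    (N, O, L) with L = (W + pl + pr - R)//stride + 1.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    pl, pr = (padding, padding) if isinstance(padding, int) else padding
    xd = x.data
    if pl or pr:
        xd = np.pad(xd, ((0, 0), (0, 0), (pl, pr)))
    N, C, Wp = xd.shape
    O, Cw, R = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    L = (Wp - R) // stride + 1
    if L < 1:
        raise ValueError(f"kernel size {R} exceeds padded width {Wp}")
    s0, s1, s2 = xd.strides
    view = np.lib.stride_tricks.as_strided(xd, (N, C, R, L), (s0, s1, s2, s2 * stride))
    col = view.reshape(N, C * R, L)  # copies
    w2 = w.data.reshape(O, C * R)
    out_data = np.matmul(w2, col)  # (N, O, L)
    del col  # keep only the padded input alive for backward
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, None)

    def _bw():
        g = out.grad  # (N, O, L)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            # strided view recomputed from the padded input: no stored
            # im2col buffer between forward and backward
            v = np.lib.stride_tricks.as_strided(
                xd, (N, C, R, L), (s0, s1, s2, s2 * stride))
            gw = np.einsum("nol,ncrl->ocr", g, v, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            dxp = np.zeros((N, C, Wp))
            dcol = np.einsum("ko,nol->nkl", w2.T, g,
                             optimize=True).reshape(N, C, R, L)
            for r in range(R):
                dxp[:, :, r: r + stride * L: stride] += dcol[:, :, r, :]
            del dcol
            if pl or pr:
                dxp = dxp[:, :, pl: Wp - pr if pr else Wp]
            x._accum(dxp)

    out._backward = _bw if out.requires_grad else None
    return out
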