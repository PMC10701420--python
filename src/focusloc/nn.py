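"""Neural-network building blocks and the Adam optimizer.

Thin layer objects over :mod:`focusloc.autodiff`: parameter
registration, train/eval mode, Linear / Conv1d / BatchNorm1d, and a
standard Adam with global-norm gradient clipping.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and submodules by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield prefix + k, v
        for mk, m in self._modules.items():
            yield from m.named_parameters(prefix + mk + ".")

    def buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray) and k.startswith("running_"):
                yield k, v
        return

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self.buffers():
            yield prefix + k, v
        for mk, m in self._modules.items():
            yield from m.named_buffers(prefix + mk + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in d.items():
            if k in params:
                params[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unknown parameter {k!r} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _kaiming(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution over (N, C, W) batches; optional zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding=(0, 0), bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = (padding, padding) if isinstance(padding, int) else tuple(padding)
        self.weight = _kaiming(rng, (c_out, c_in, kernel), c_in * kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalisation over (N, C, W): statistics per channel."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, n_ch, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, n_ch, 1))
        self.running_var = np.ones((1, n_ch, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            return self.gamma * (centred * (var + self.eps) ** -0.5) + self.beta
        xhat = (x - Tensor(self.running_mean)) * Tensor(
            (self.running_var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: Optional[float] = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
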