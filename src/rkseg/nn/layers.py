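"""Layer/module abstractions over the autodiff engine, plus the optimizer."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and submodules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        idx = len(self._items)
        self._items.append(m)
        self._modules[str(idx)] = m

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Conv2d(Module):
    """3x3 (same-padded) or 1x1 convolution with He-normal init and bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(dtype), requires_grad=True, name="weight")
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True,
                           name="bias")

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True,
                            name="gamma")
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True,
                           name="beta")

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class Identity(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """Stochastic gradient descent with Nesterov momentum.

    Uses the common deep-learning update: ``v <- m*v + g`` followed by
    ``p <- p - lr*(g + m*v)``.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0, nesterov: bool = True):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.momentum
            v += g
            if self.nesterov:
                p.data -= self.lr * (g + self.momentum * v)
            else:
                p.data -= self.lr * v
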