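"""Neural-network building blocks on top of :mod:`resswin.autodiff`.

Modules hold :class:`Parameter` leaves and non-trainable buffers (batch-norm
running statistics).  Initialisation is fully deterministic: every layer
draws its weights from the ``numpy.random.Generator`` it is given, so two
models built from generators with the same seed have identical weights.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "BatchNorm2d",
    "Adam",
    "trunc_normal",
    "count_parameters",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draw clipped to two standard deviations (transformer init)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2.0 * std, 2.0 * std)


class Module:
    """Minimal container with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    def _children(self, prefix: str = "") -> Iterator[tuple[str, object]]:
        """Named Parameter and Module leaves, descending nested lists/tuples."""

        def walk(name: str, value):
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            yield from walk(f"{prefix}{name}", value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, child in self._children(prefix):
            if isinstance(child, Parameter):
                yield name, child
            else:
                yield from child.named_parameters(f"{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in self._children(prefix):
            if isinstance(child, Module):
                yield from child.named_buffers(f"{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            if isinstance(child, Module):
                yield from child.modules()

    # -- state -------------------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif name in buffers:
                np.copyto(buffers[name], value)
            else:
                raise KeyError(f"unknown state entry {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    """Total number of trainable scalars (weights, biases, norm affines)."""
    return int(sum(p.size for p in module.parameters()))


# ---------------------------------------------------------------------------


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred * ad.power(var + self.eps, -0.5)
        return xhat * self.weight + self.bias


class Conv2d(Module):
    """Stride-1 same-padding convolution over (N, C, H, W) features."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))  # He init for ReLU branches
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation over (N, C, H, W); running stats used in eval mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xhat = centred * ad.power(var + self.eps, -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Adam(Module):
    """Adam optimiser (beta1=0.9, beta2=0.999), matching the common defaults."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
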