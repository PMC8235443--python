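"""Parameterised building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: expected {p.data.shape}, got {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


def _glorot(rng, shape, fan_in: int, fan_out: int, dtype, gain: float = 1.0) -> np.ndarray:
    """Glorot-uniform init.

    ``gain=4`` is the classic correction for sigmoid-activated layers,
    whose linear regime is four times shallower than tanh's; without it
    signal variance collapses through stacked sigmoid stages.
    """
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32, gain: float = 1.0):
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out, dtype, gain), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b


class Conv2d(Module):
    """Same-padded stride-1 convolution on (B, H, W, C) inputs."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32, gain: float = 1.0):
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.w = Tensor(_glorot(rng, (k, k, c_in, c_out), fan_in, fan_out, dtype, gain), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)


class GroupedConv1d(Module):
    """Per-group (here: per accelerometer axis) 1-D convolution bank."""

    def __init__(self, groups: int, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32, gain: float = 1.0):
        fan_in, fan_out = k * cin, k * cout
        self.w = Tensor(_glorot(rng, (k, groups, cin, cout), fan_in, fan_out, dtype, gain), requires_grad=True)
        self.b = Tensor(np.zeros(groups * cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.grouped_conv1d(x, self.w, self.b)


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
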