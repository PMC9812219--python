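"""Layers and optimizer for the targeting models."""

from __future__ import annotations

import numpy as np

from cryotarget.nn import functional as F
from cryotarget.nn.autograd import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "Linear", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable container; parameters are discovered by attribute walk."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    walk(value)
                elif isinstance(value, (list, tuple)):
                    for item in value:
                        if isinstance(item, Module):
                            walk(item)
                        elif isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict for single-file checkpoints -------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model needs {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr


class Conv2d(Module):
    """3x3 (or kxk) same convolution with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (out_channels, in_channels,
                                            kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class Adam:
    """Adam with optional per-parameter bounds (used to keep sigma positive)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.lower: dict[int, float] = {}

    def set_lower_bound(self, param: Parameter, lo: float) -> None:
        for i, p in enumerate(self.params):
            if p is param:
                self.lower[i] = lo
                return
        raise ValueError("parameter not managed by this optimizer")

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if i in self.lower:
                p.data = np.maximum(p.data, self.lower[i])

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
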