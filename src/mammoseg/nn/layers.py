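"""Neural-network building blocks on top of the autodiff tensor engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Parameter, Tensor

__all__ = ["Module", "Linear", "Conv3d", "LayerNorm", "InstanceNorm3d", "ModuleList"]


class Module:
    """Base class; discovers parameters/submodules by attribute walking."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in self.__dict__.values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(v, Parameter):
                        out.append((f"{key}.{i}", v))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m):
        self.items.append(m)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (in_features, out_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """Stride-1 'same'-padded 3-D convolution; kernel sizes may be even per axis
    only if 1 (anisotropic 3x3x1 kernels are the intended use)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int], rng: np.random.Generator,
                 bias: bool = True):
        fan_in = in_channels * int(np.prod(kernel))
        bound = math.sqrt(2.0 / fan_in)  # He init for (leaky-)relu nets
        self.weight = Parameter(
            (rng.standard_normal((out_channels, in_channels) + tuple(kernel)) * bound
             ).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.padding = tuple(k // 2 for k in kernel)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, self.padding)


class LayerNorm(Module):
    """Normalization over the trailing feature axis (token layout)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes (N,C,H,W,D)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta
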