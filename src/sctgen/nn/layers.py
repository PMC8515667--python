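"""Layer/module abstractions over the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    conv2d,
    conv_transpose2d,
    instance_norm,
)

DTYPE = np.float32


class Module:
    """Minimal container: tracks sub-modules and parameters by attribute."""

    def __call__(self, x):
        return self.forward(x)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Tensor):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{path}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _init(rng: np.random.Generator, shape, scale: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, padding: int = 0,
                 pad_mode: str = "zero", bias: bool = True, *, rng: np.random.Generator):
        self.weight = _init(rng, (cout, cin, k, k))
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True) if bias else None
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.pad_mode)

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2, padding: int = 1,
                 output_padding: int = 1, bias: bool = True, *, rng: np.random.Generator):
        self.weight = _init(rng, (cin, cout, k, k))
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.padding, self.output_padding)

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """Reflect-padded 3x3 conv pair with instance norm; additive skip."""

    def __init__(self, channels: int, *, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x):
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h
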