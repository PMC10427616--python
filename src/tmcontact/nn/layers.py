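"""Layer/module abstractions on top of the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "InstanceNorm2d", "Conv2d"]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data, dtype=None):
        from . import layers as _self  # module attr lookup keeps DTYPE patchable
        super().__init__(np.asarray(data, dtype=dtype or _self.DTYPE), requires_grad=True)


class Module:
    """Named-parameter container with state-dict (de)serialisation."""

    def modules(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, mod in self.modules():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) - set(state)
            extra = set(state) - set(mine)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in mine.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """Dense map applied over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float = 1.0):
        std = scale / np.sqrt(d_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)

    def zero_init(self):
        """Set weight and bias to zero (used for identity-residual checks)."""
        self.weight.data[...] = 0.0
        self.bias.data[...] = 0.0


class LayerNorm(Module):
    """Normalisation over the channel (last) axis with affine parameters."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.affine_norm(x, self.gamma, self.beta, axes=-1, eps=self.eps)


class InstanceNorm2d(Module):
    """Normalisation over the two spatial axes, per channel (single sample)."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.affine_norm(x, self.gamma, self.beta, axes=(0, 1), eps=self.eps)


class Conv2d(Module):
    """Same-padding square convolution, channels-last, single sample."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 scale: float = 1.0, bias: bool = True):
        fan_in = kernel * kernel * c_in
        std = scale / np.sqrt(fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)

    def zero_init(self):
        self.weight.data[...] = 0.0
        if self.bias is not None:
            self.bias.data[...] = 0.0
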