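"""Parameterized layers on top of the autodiff engine.

Convolutions are bias-free throughout (zero inputs propagate to zero
outputs and the transposed-attention algebra stays clean); the only biased
layers are the small perceptrons that map the time embedding to channel-wise
modulation arrays.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Named-parameter container with Restormer-style nesting."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (float32 for fast training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1x1(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, scale, (c_out, c_in)))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1x1(x, self.weight)


class DWConv3x3(Module):
    def __init__(self, c: int, rng: np.random.Generator):
        self.kernel = Parameter(rng.normal(0.0, np.sqrt(1.0 / 9.0), (c, 3, 3)))

    def forward(self, x: Tensor) -> Tensor:
        return ad.dwconv3x3(x, self.kernel)


class Conv3x3(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / (9.0 * c_in))
        self.weight = Parameter(rng.normal(0.0, scale, (c_out, c_in, 3, 3)))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3x3(x, self.weight)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(rng.normal(0.0, np.sqrt(1.0 / n_in), (n_out, n_in)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    """Bias-free channel layer norm for NCHW features."""

    def __init__(self, c: int):
        self.gain = Parameter(np.ones(c))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layernorm_channels(x, self.gain)
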