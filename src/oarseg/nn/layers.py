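"""Stateful layer objects holding trainable parameters."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tape import Tensor

__all__ = ["Module", "Conv3d", "ConvTranspose3d", "InstanceNorm3d"]


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            items = obj if isinstance(obj, (list, tuple)) else [obj]
            for it in items:
                if isinstance(it, Tensor) and it.requires_grad and id(it) not in seen:
                    seen.add(id(it))
                    params.append(it)
                elif isinstance(it, Module):
                    for p in it.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv3d(Module):
    """Zero-padded stride-1 cubic convolution (kernel size 1 or 3)."""

    def __init__(self, in_channels, out_channels, kernel_size, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        k = int(kernel_size)
        fan_in = in_channels * k**3
        self.weight = Tensor(
            _he_init(rng, (out_channels, in_channels, k, k, k), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Stride-2 transpose convolution with 2x2x2 kernel (doubles resolution)."""

    def __init__(self, in_channels, out_channels, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = in_channels * 8
        self.weight = Tensor(
            _he_init(rng, (in_channels, out_channels, 2, 2, 2), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Affine instance normalisation (statistics per channel per volume)."""

    def __init__(self, channels, eps: float = 1e-5, *, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)
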