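"""Trainable layers built on the autograd engine.

Weight layout follows the common CNN convention: convolution kernels
are ``(C_out, C_in, kh, kw)``, transposed-convolution kernels
``(C_in, C_out, kh, kw)``, linear weights ``(K, M)``. Initialization
is variance-scaled (He) from an explicit per-model random generator,
so a model is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Conv2d", "ConvTranspose2d", "Linear", "Module"]


class Module:
    """Base with recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2d(Module):
    """2-D convolution preserving or striding spatial size.

    ``stride=1`` pads by ``k // 2`` (reflection by default, so the fov
    rim is not darkened); ``stride=2`` uses zero padding 1 with a 3x3
    kernel, halving even spatial sizes.
    """

    def __init__(self, rng, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, pad_mode: str = "reflect", dtype=np.float32):
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.pad_mode = pad_mode
        self.w = Tensor(_he(rng, (out_channels, in_channels, k, k), in_channels * k * k, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        pad = self.kernel_size // 2
        if pad:
            if self.pad_mode == "reflect" and self.stride == 1:
                x = ag.reflect_pad2d(x, pad)
            else:
                x = ag.zero_pad2d(x, pad)
        return ag.conv2d(x, self.w, self.b, stride=self.stride)


class ConvTranspose2d(Module):
    """3x3 transposed convolution doubling spatial size (stride 2)."""

    def __init__(self, rng, in_channels: int, out_channels: int, dtype=np.float32):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = Tensor(_he(rng, (in_channels, out_channels, 3, 3), in_channels * 9, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.w, self.b, stride=2, padding=1, output_padding=1)


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int, dtype=np.float32):
        self.w = Tensor(_he(rng, (in_features, out_features), in_features, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.w, self.b)
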