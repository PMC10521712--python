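"""Layer primitives built on the autodiff engine.

Parameter initialization takes an explicit ``numpy.random.Generator`` so
that model construction is a pure function of (spec, seed).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, maxpool2x2, resize_bilinear


class Module:
    """Minimal module base: named parameter traversal and train/eval hooks."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 'same' (or 'valid') convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True,
                 padding: int | None = None):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class DoubleConv(Module):
    """Two 3x3 convolutions with ReLU activations (the classic UNET block)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 mid_ch: int | None = None):
        mid_ch = out_ch if mid_ch is None else mid_ch
        self.conv1 = Conv2d(in_ch, mid_ch, 3, rng)
        self.conv2 = Conv2d(mid_ch, out_ch, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class Upsample2x(Module):
    """Bilinear 2x upsampling (no learnable parameters)."""

    def forward(self, x: Tensor) -> Tensor:
        return resize_bilinear(x, x.shape[2] * 2, x.shape[3] * 2)


class AttentionGate(Module):
    """Additive attention gate for skip connections.

    Projects the encoder map and the (upsampled) decoder gating signal to an
    intermediate width, sums, applies ReLU, maps to a scalar per pixel,
    squashes with a sigmoid, and scales the encoder map by the resulting
    coefficients in (0, 1).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 inter_channels: int | None = None):
        inter = max(1, channels // 2) if inter_channels is None else inter_channels
        self.theta = Conv2d(channels, inter, 1, rng)   # encoder projection
        self.phi = Conv2d(channels, inter, 1, rng)     # gating projection
        self.psi = Conv2d(inter, 1, 1, rng)

    def coefficients(self, x_enc: Tensor, x_dec: Tensor) -> Tensor:
        if x_enc.shape[2:] != x_dec.shape[2:]:
            raise ValueError("attention gate: spatial dims must match")
        return self.psi((self.theta(x_enc) + self.phi(x_dec)).relu()).sigmoid()

    def forward(self, x_enc: Tensor, x_dec: Tensor) -> Tensor:
        return x_enc * self.coefficients(x_enc, x_dec)


def fuse_concat(a: Tensor, x_dec: Tensor) -> Tensor:
    """Skip fusion by channel concatenation (skip features first)."""
    if a.shape[2:] != x_dec.shape[2:]:
        raise ValueError(
            f"fuse_concat: spatial dims differ {a.shape[2:]} vs {x_dec.shape[2:]}")
    return concat([a, x_dec], axis=1)


def fuse_multiply(h: Tensor, x_dec: Tensor) -> Tensor:
    """Skip fusion by elementwise (Hadamard) product; keeps channel count."""
    if h.shape != x_dec.shape:
        raise ValueError(
            f"fuse_multiply: shapes differ {h.shape} vs {x_dec.shape}")
    return h * x_dec
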