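"""Learnable spatial histogram features for convolutional feature maps.

A histogram block turns D convolutional feature maps into D statistical
texture maps in three steps:

1. a learned 1x1 projection reduces the D input channels to K channels;
2. each of the K channels is softly assigned to B histogram bins through a
   Gaussian radial-basis response ``exp(-gamma_bk^2 (x - mu_bk)^2)`` with
   learnable bin centres ``mu`` and widths ``gamma``;
3. the soft assignments are averaged over a local S x T spatial window,
   giving normalized local bin counts in (0, 1].

Because B*K = D is enforced, the block conserves the channel count and can
replace (or augment) a plain skip connection in an encoder-decoder network.
The output channel ordering is bin-major within each reduced channel:
channel ``k`` occupies output slots ``k*B .. k*B + B - 1``.

Both a functional numpy interface (channels-last ``(H, W, C)`` arrays, used
for analysis and testing) and an autodiff layer (``HistogramLayer``,
channels-first tensors, used inside networks) are provided; they share the
same computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Tensor, box_mean, pad2d, resize_bilinear
from .nn.layers import Conv2d


@dataclass
class BinParams:
    """Learnable histogram bin centres and widths, one pair per (bin, channel).

    Widths enter the response only squared, so the layer is invariant to the
    sign of any width entry.
    """

    centers: np.ndarray  # shape (B, K)
    widths: np.ndarray   # shape (B, K)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.widths = np.asarray(self.widths, dtype=np.float64)
        if self.centers.shape != self.widths.shape:
            raise ValueError("centers and widths must have identical shape")
        if self.centers.ndim != 2:
            raise ValueError("centers/widths must be 2-D (bins, channels)")

    @property
    def n_bins(self) -> int:
        return self.centers.shape[0]

    @property
    def n_channels(self) -> int:
        return self.centers.shape[1]

    @classmethod
    def initialize(cls, n_bins: int, n_channels: int,
                   span: float = 2.0) -> "BinParams":
        """Default init: centres linearly spaced on [-span, span] for every
        channel, widths constant at B/4 so adjacent bins overlap moderately."""
        centers = np.tile(np.linspace(-span, span, n_bins)[:, None],
                          (1, n_channels))
        widths = np.full((n_bins, n_channels), n_bins / 4.0)
        return cls(centers, widths)


@dataclass
class HistogramBlockConfig:
    """Hyperparameters of one histogram block.

    ``bins * reduced_channels`` must equal ``input_channels`` so the block
    conserves the channel count of the skip connection it sits on.
    """

    input_channels: int
    bins: int
    reduced_channels: int
    window: tuple[int, int] = (2, 2)
    spatial_mode: str = "preserve"
    init_span: float = 2.0

    def __post_init__(self):
        if self.bins < 1 or self.reduced_channels < 1 or self.input_channels < 1:
            raise ValueError("channel/bin counts must be positive")
        if self.bins * self.reduced_channels != self.input_channels:
            raise ValueError(
                f"bins * reduced_channels must equal input_channels "
                f"({self.bins} * {self.reduced_channels} != {self.input_channels})")
        s, t = self.window
        if s < 1 or t < 1:
            raise ValueError("window dims must be >= 1")
        if self.spatial_mode not in ("preserve", "pool"):
            raise ValueError("spatial_mode must be 'preserve' or 'pool'")

    def for_channels(self, channels: int) -> "HistogramBlockConfig":
        """Re-target this config to a level with a different channel count,
        keeping the bin count and window."""
        if channels % self.bins:
            raise ValueError(f"{self.bins} bins do not divide {channels} channels")
        return HistogramBlockConfig(channels, self.bins, channels // self.bins,
                                    self.window, self.spatial_mode,
                                    self.init_span)


def rbf_bin_response(x: float, mu: float, gamma: float) -> float:
    """Soft assignment of value ``x`` to a bin: exp(-gamma^2 (x - mu)^2).

    Equals 1 exactly when ``x == mu`` or ``gamma == 0``; strictly positive;
    symmetric in ``x - mu`` and in the sign of ``gamma``.
    """
    x, mu, gamma = float(x), float(mu), float(gamma)
    if not (np.isfinite(x) and np.isfinite(mu) and np.isfinite(gamma)):
        raise ValueError("rbf_bin_response requires finite inputs")
    return float(np.exp(-(gamma ** 2) * (x - mu) ** 2))


def reduce_channels(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-pixel linear projection of channels: (H, W, D) @ (K, D)^T -> (H, W, K).

    No bias and no nonlinearity: the projection is purely a dimension
    reducer ahead of the binning step.
    """
    x = np.asarray(x, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected channels-last (H, W, D) input")
    if weights.ndim != 2 or weights.shape[1] != x.shape[2]:
        raise ValueError(
            f"weights (K, D) incompatible with input D={x.shape[2]}: "
            f"{weights.shape}")
    return x @ weights.T


def _soft_counts(x: np.ndarray, bins: BinParams) -> np.ndarray:
    # (H, W, K) -> (H, W, K, B) RBF responses
    diff = x[..., None] - bins.centers.T[None, None, :, :]
    return np.exp(-(bins.widths.T[None, None, :, :] ** 2) * diff ** 2)


def local_histogram(x: np.ndarray, bins: BinParams,
                    window: tuple[int, int] = (2, 2),
                    spatial_mode: str = "preserve") -> np.ndarray:
    """Window-averaged soft bin counts of a (H, W, K) map -> (H, W, B*K).

    Every output value is the mean of B*K RBF responses over an S x T
    neighbourhood, so it lies in (0, 1].  In ``preserve`` mode the window
    slides with stride 1 over a replicate-padded map and the spatial size is
    unchanged; in ``pool`` mode the window strides by its own size and the
    result is bilinearly resized back.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected channels-last (H, W, K) input")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if bins.n_channels != x.shape[2]:
        raise ValueError(
            f"bins expect {bins.n_channels} channels, input has {x.shape[2]}")
    s, t = window
    h, w, k = x.shape
    if s > h + s - 1 or t > w + t - 1:  # unreachable for s,t>=1; guard anyway
        raise ValueError("window larger than padded input")
    resp = _soft_counts(x, bins)                        # (H, W, K, B)
    resp = resp.reshape(h, w, k * bins.n_bins)          # bin-major per channel
    tensor = Tensor(resp.transpose(2, 0, 1)[None])      # (1, KB, H, W)
    out = _window_average(tensor, s, t, spatial_mode, h, w)
    return out.data[0].transpose(1, 2, 0)


def _window_average(resp: Tensor, s: int, t: int, spatial_mode: str,
                    h: int, w: int) -> Tensor:
    if spatial_mode == "preserve":
        padded = pad2d(resp, (0, s - 1, 0, t - 1), mode="replicate")
        return box_mean(padded, s, t, stride=1)
    # pool: pad up to a multiple of the window, stride by it, resize back
    if s != t:
        raise ValueError("pool mode requires a square window")
    pad_h = (-h) % s
    pad_w = (-w) % t
    if pad_h or pad_w:
        resp = pad2d(resp, (0, pad_h, 0, pad_w), mode="replicate")
    pooled = box_mean(resp, s, t, stride=s)
    return resize_bilinear(pooled, h, w)


class HistogramLayer(Module):
    """Autodiff histogram block: 1x1 reduction then windowed soft binning.

    Input and output are channels-first tensors of identical shape
    ``(N, D, H, W)``; bin centres, widths and the reduction weights are all
    learnable.
    """

    def __init__(self, config: HistogramBlockConfig, rng: np.random.Generator):
        self.config = config
        self.reduce = Conv2d(config.input_channels, config.reduced_channels,
                             1, rng, bias=False)
        init = BinParams.initialize(config.bins, config.reduced_channels,
                                    config.init_span)
        self.centers = Tensor(init.centers, requires_grad=True)
        self.widths = Tensor(init.widths, requires_grad=True)

    def bin_params(self) -> BinParams:
        return BinParams(self.centers.data.copy(), self.widths.data.copy())

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[1] != cfg.input_channels:
            raise ValueError(
                f"histogram block expects {cfg.input_channels} channels, "
                f"got {x.shape[1]}")
        n, _, h, w = x.shape
        xr = self.reduce(x)                                    # (N, K, H, W)
        xe = xr.reshape(n, cfg.reduced_channels, 1, h, w)
        mu = self.centers.transpose(1, 0).reshape(1, cfg.reduced_channels,
                                                  cfg.bins, 1, 1)
        ga = self.widths.transpose(1, 0).reshape(1, cfg.reduced_channels,
                                                 cfg.bins, 1, 1)
        diff = xe - mu
        resp = (diff * diff * (ga * ga) * -1.0).exp()
        resp = resp.reshape(n, cfg.input_channels, h, w)       # k*B + b order
        s, t = cfg.window
        return _window_average(resp, s, t, cfg.spatial_mode, h, w)


def histogram_block(x: np.ndarray, config: HistogramBlockConfig,
                    reduce_weights: np.ndarray,
                    bins: BinParams) -> np.ndarray:
    """Functional histogram block on a channels-last (H, W, D) array.

    Composition ``reduce_channels`` -> ``local_histogram``; conserves both
    the spatial size and the channel count (B*K = D).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != config.input_channels:
        raise ValueError(
            f"expected (H, W, {config.input_channels}) input, got {x.shape}")
    reduced = reduce_channels(x, reduce_weights)
    return local_histogram(reduced, bins, config.window, config.spatial_mode)
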