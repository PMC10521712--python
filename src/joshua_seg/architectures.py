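"""The five comparison networks: UNET, UNET+, attention UNET, JOSHUA, JOSHUA+.

All variants share one encoder-decoder skeleton: a double-convolution
(3x3 + ReLU, twice) stem, ``depth`` max-pool down-steps doubling the channel
width, bilinear 2x upsampling in the decoder, and a 1x1 sigmoid head.  The
deepest block keeps the width of the last skip level (rather than doubling
again), which makes the upsampled decoder map at every level have exactly
the channel count of the same-level skip — a requirement for elementwise
fusion.  The variants differ only in what travels along the skip
connections and how it is fused into the decoder:

================  ==========================  =====================
variant           skip transform              fusion
================  ==========================  =====================
``unet``          identity                    channel concatenation
``unet_plus``     identity                    elementwise product
``attention_unet`` additive attention gate    channel concatenation
``joshua``        histogram block             channel concatenation
``joshua_plus``   histogram block             elementwise product
================  ==========================  =====================

Concatenation doubles the decoder input width; the elementwise product
keeps it, which removes roughly 18% of the learnable parameters at the
default width (depth 4, 64 base channels).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .histogram_core import HistogramBlockConfig, HistogramLayer
from .nn import (AttentionGate, Conv2d, DoubleConv, MaxPool2, Module, Tensor,
                 Upsample2x, fuse_concat, fuse_multiply)

VARIANTS = ("unet", "unet_plus", "attention_unet", "joshua", "joshua_plus")
_MULTIPLY_VARIANTS = ("unet_plus", "joshua_plus")
_HISTOGRAM_VARIANTS = ("joshua", "joshua_plus")


class ConfigError(ValueError):
    """Invalid or inconsistent model specification."""


class ResizeRequiredError(ValueError):
    """Input spatial dims are not divisible by 2**depth; caller must resize."""


@dataclass
class ModelSpec:
    """Declarative description of a segmentation network.

    A spec plus a seed reconstructs a network with bit-identical initial
    parameters.
    """

    variant: str = "unet"
    depth: int = 4
    base_channels: int = 64
    out_classes: int = 1
    histogram: HistogramBlockConfig | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; "
                              f"choose from {VARIANTS}")
        if self.depth < 1 or self.base_channels < 1:
            raise ConfigError("depth and base_channels must be positive")
        if self.out_classes != 1:
            raise ConfigError("only binary (out_classes=1) heads are supported")
        if self.variant in _HISTOGRAM_VARIANTS:
            if self.histogram is None:
                raise ConfigError(
                    f"{self.variant} requires a histogram block config")
            for ch in self.skip_channels:
                self.histogram.for_channels(ch)  # raises if B does not divide

    @property
    def skip_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.histogram is not None:
            d["histogram"]["window"] = list(self.histogram.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        hist = d.pop("histogram", None)
        if hist is not None:
            hist = dict(hist)
            hist["window"] = tuple(hist.get("window", (2, 2)))
            hist = HistogramBlockConfig(**hist)
        return cls(histogram=hist, **d)


class SegmentationModel(Module):
    """Assembled encoder-decoder network for one :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        chans = spec.skip_channels                       # e.g. [64,128,256,512]
        bottleneck = chans[-1]
        self.inc = DoubleConv(3, chans[0], rng)
        self.pool = MaxPool2()
        self.up = Upsample2x()
        self.downs = [DoubleConv(chans[i - 1], chans[i], rng)
                      for i in range(1, spec.depth)]
        self.bottom = DoubleConv(chans[-1], bottleneck, rng)
        self.skips: list[Module] = []
        if spec.variant in _HISTOGRAM_VARIANTS:
            self.skips = [HistogramLayer(spec.histogram.for_channels(c), rng)
                          for c in chans]
        elif spec.variant == "attention_unet":
            self.skips = [AttentionGate(c, rng) for c in chans]
        concat_fusion = spec.variant not in _MULTIPLY_VARIANTS
        self.ups = []
        for i in reversed(range(spec.depth)):            # deepest level first
            d = chans[i]
            out_ch = chans[i - 1] if i > 0 else chans[0]
            fused = 2 * d if concat_fusion else d
            self.ups.append(DoubleConv(fused, out_ch, rng, mid_ch=d))
        self.head = Conv2d(chans[0], spec.out_classes, 1, rng)

    @property
    def parameter_count(self) -> int:
        return self.num_parameters()

    def forward(self, x: Tensor) -> Tensor:
        """Map (N, 3, H, W) images to (N, 1, H, W) probability maps."""
        spec = self.spec
        h, w = x.shape[2], x.shape[3]
        div = 2 ** spec.depth
        if h % div or w % div:
            raise ResizeRequiredError(
                f"input {h}x{w} not divisible by 2^{spec.depth}; resize first")
        feats = []
        cur = self.inc(x)
        feats.append(cur)
        for blk in self.downs:
            cur = blk(self.pool(cur))
            feats.append(cur)
        cur = self.bottom(self.pool(cur))
        for lvl, blk in zip(reversed(range(spec.depth)), self.ups):
            dec = self.up(cur)
            skip = feats[lvl]
            if spec.variant in _HISTOGRAM_VARIANTS:
                skip = self.skips[lvl](skip)
            elif spec.variant == "attention_unet":
                skip = self.skips[lvl](skip, dec)
            if spec.variant in _MULTIPLY_VARIANTS:
                cur = blk(fuse_multiply(skip, dec))
            else:
                cur = blk(fuse_concat(skip, dec))
        return self.head(cur).sigmoid()


def build_model(spec: ModelSpec, seed: int) -> SegmentationModel:
    """Construct a network deterministically from a spec and a seed."""
    return SegmentationModel(spec, np.random.default_rng(seed))


def count_parameters(model: SegmentationModel) -> int:
    """Total size of all trainable parameter arrays (histogram bin centres
    and widths included)."""
    return model.num_parameters()


def predict_mask(model: SegmentationModel, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Segment one channels-last RGB image into a binary {0,1} mask.

    The probability map comes from the sigmoid head; a pixel is positive
    when its probability is >= ``threshold`` (ties go to the positive
    class).
    """
    probs = predict_probabilities(model, image)
    return (probs >= threshold).astype(np.uint8)


def predict_probabilities(model: SegmentationModel,
                          image: np.ndarray) -> np.ndarray:
    """Forward one (H, W, 3) image in [0, 1]; returns the (H, W) sigmoid map."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a channels-last (H, W, 3) RGB image")
    x = Tensor(arr.transpose(2, 0, 1)[None])
    return model(x).data[0, 0]


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Write parameters + spec as one archive (npz with a JSON spec entry)."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__spec__"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    """Rebuild a model from an archive; re-validates the stored spec."""
    with np.load(path) as data:
        spec = ModelSpec.from_dict(
            json.loads(bytes(data["__spec__"].tobytes()).decode()))
        model = build_model(spec, seed=0)
        stored = {k: data[k] for k in data.files if k != "__spec__"}
    for name, p in model.named_parameters():
        if name not in stored:
            raise ConfigError(f"checkpoint missing parameter {name!r}")
        if stored[name].shape != p.data.shape:
            raise ConfigError(f"checkpoint parameter {name!r} has shape "
                              f"{stored[name].shape}, expected {p.data.shape}")
        p.data = stored[name].astype(np.float64)
    return model
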