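"""Image/mask I/O, augmentation, cross-validation splits and synthetic data.

The synthetic generator emulates H&E (or Masson's trichrome) stained
sections containing adipocytes: white elliptical cells with a thin darker
membrane ring on a smoothly varying stained background.  Ground-truth masks
mark the ellipse interiors.  The generated adipose fraction is controllable
down to the "adipose-poor" regime (< 1% positive pixels) so that the class
imbalance of real histology is reproduced.  Generation is a pure function
of its spec: identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize as sk_resize
from sklearn.model_selection import KFold, StratifiedKFold

WEEKS = (1, 2, 4, 8)
CONDITIONS = ("silk", "silk-collagen", "silk-heparin", "silk+VEGF S")
FOLD_SCHEMES = ("random_kfold", "stratified_time", "stratified_condition",
                "fold_by_week", "validate_week8")

# Stain palettes (RGB in [0,1]); fixed here so realism can be tuned in one
# place without touching generator logic.
PALETTES = {
    "HE": {
        "background": (0.89, 0.70, 0.80),   # eosin pink
        "blotch": (0.55, 0.40, 0.68),       # hematoxylin purple
        "adipocyte": (0.97, 0.96, 0.97),    # lipid-dissolved white
        "membrane": (0.62, 0.48, 0.60),
    },
    "trichrome": {
        "background": (0.45, 0.55, 0.78),   # collagen blue
        "blotch": (0.72, 0.30, 0.35),       # muscle/keratin red
        "adipocyte": (0.97, 0.97, 0.96),
        "membrane": (0.40, 0.42, 0.58),
    },
}


class GenerationError(RuntimeError):
    """Synthetic image constraints could not be satisfied."""


@dataclass
class HistImage:
    """An RGB image with optional acquisition metadata."""

    pixels: np.ndarray                    # (H, W, 3) float in [0, 1]
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be channels-last RGB")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic histology dataset."""

    n_images: int = 32
    height: int = 64
    width: int = 64
    adipose_fraction_range: tuple[float, float] = (0.05, 0.35)
    n_blobs_range: tuple[int, int] = (2, 8)
    blob_axis_range: tuple[float, float] = (4.0, 12.0)
    membrane_width: float = 1.5
    stain: str = "HE"
    noise_sd: float = 0.02
    reference_length: float = 0.5         # microns per full-resolution pixel
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.adipose_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("adipose_fraction_range must satisfy 0<=lo<=hi<=1")
        if self.n_blobs_range[0] > self.n_blobs_range[1]:
            raise ValueError("empty n_blobs_range")
        if self.blob_axis_range[0] > self.blob_axis_range[1]:
            raise ValueError("empty blob_axis_range")
        if self.stain not in PALETTES:
            raise ValueError(f"unknown stain {self.stain!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path, id: str | None = None,
               metadata: dict | None = None) -> HistImage:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    return HistImage(arr, id=id or Path(path).stem, metadata=metadata or {})


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    vals = set(np.unique(arr).tolist())
    if not (vals <= {0, 1} or vals <= {0, 255}):
        raise ValueError(f"mask {path} is not binary: values {sorted(vals)[:10]}")
    return (arr > 0).astype(np.uint8)


def load_pair(image_path: str | Path, mask_path: str | Path,
              metadata: dict | None = None) -> tuple[HistImage, np.ndarray]:
    """Load an image and its binary mask; shapes must agree."""
    img = load_image(image_path, metadata=metadata)
    mask = load_mask(mask_path)
    if mask.shape != img.pixels.shape[:2]:
        raise ValueError(f"image {img.pixels.shape[:2]} and mask {mask.shape} "
                         "shapes disagree")
    return img, mask


def save_pair(img: HistImage, mask: np.ndarray, image_path: str | Path,
              mask_path: str | Path) -> None:
    Image.fromarray(
        np.round(img.pixels * 255).astype(np.uint8)).save(image_path)
    Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)


def resize_pair(img: HistImage, mask: np.ndarray,
                target: tuple[int, int] = (256, 256)
                ) -> tuple[HistImage, np.ndarray]:
    """Bilinear image resize; nearest-neighbour mask resize (stays binary).

    The original dims are recorded in the image metadata so physical-area
    back-scaling remains possible after downsampling.
    """
    h0, w0 = img.pixels.shape[:2]
    pixels = sk_resize(img.pixels, target, order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    new_mask = sk_resize(mask.astype(np.float64), target, order=0, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    meta = dict(img.metadata)
    meta.setdefault("original_height", h0)
    meta.setdefault("original_width", w0)
    out = HistImage(np.clip(pixels, 0, 1), id=img.id, metadata=meta)
    return out, (new_mask > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    flip_p: float = 0.5
    jitter_p: float = 0.5
    hue_p: float = 0.05
    brightness: float = 0.25
    contrast: float = 0.25
    saturation: float = 0.25
    hue: float = 0.05
    crop: tuple[int, int] | None = None   # GlaS-style random crops


def augment(img: HistImage, mask: np.ndarray, rng: np.random.Generator,
            config: AugmentConfig | None = None
            ) -> tuple[HistImage, np.ndarray]:
    """Random flip, right-angle rotation and colour jitter.

    Geometric transforms apply identically to image and mask; colour jitter
    touches the image only, so labels are never perturbed.  Deterministic
    for a given generator state.
    """
    cfg = config or AugmentConfig()
    pix = img.pixels
    if cfg.crop is not None:
        ch, cw = cfg.crop
        h, w = pix.shape[:2]
        if ch > h or cw > w:
            raise ValueError(f"crop {cfg.crop} larger than image {(h, w)}")
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        pix = pix[top:top + ch, left:left + cw]
        mask = mask[top:top + ch, left:left + cw]
    if rng.random() < cfg.flip_p:
        pix = pix[:, ::-1]
        mask = mask[:, ::-1]
    k = int(rng.integers(0, 4))           # uniform over 0/90/180/270 degrees
    if k:
        pix = np.rot90(pix, k)
        mask = np.rot90(mask, k)
    if rng.random() < cfg.jitter_p:       # brightness
        pix = pix * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if rng.random() < cfg.jitter_p:       # contrast about the image mean
        f = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
        pix = (pix - pix.mean()) * f + pix.mean()
    if rng.random() < cfg.jitter_p:       # saturation about the grey image
        f = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
        grey = pix.mean(axis=2, keepdims=True)
        pix = grey + (pix - grey) * f
    if rng.random() < cfg.hue_p:
        hsv = skcolor.rgb2hsv(np.clip(pix, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue, cfg.hue)) % 1.0
        pix = skcolor.hsv2rgb(hsv)
    out = HistImage(np.clip(pix, 0, 1).copy(), id=img.id,
                    metadata=dict(img.metadata))
    return out, np.ascontiguousarray(mask)


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Mapping of image ids to validation-fold indices.

    For the k-fold schemes the folds partition the ids and fold ``f`` is the
    validation set of run ``f``.  For ``validate_week8`` there is a single
    split: fold 0 is the (week-8) validation set and fold -1 the training
    set.
    """

    scheme: str
    k: int
    mapping: dict[str, int]
    seed: int

    def splits(self) -> list[tuple[list[str], list[str]]]:
        """(train_ids, val_ids) per cross-validation run."""
        ids = list(self.mapping)
        if self.scheme == "validate_week8":
            val = [i for i in ids if self.mapping[i] == 0]
            train = [i for i in ids if self.mapping[i] != 0]
            return [(train, val)]
        out = []
        for f in range(self.k):
            val = [i for i in ids if self.mapping[i] == f]
            train = [i for i in ids if self.mapping[i] != f]
            out.append((train, val))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": list(self.mapping),
                             "fold": list(self.mapping.values())})


def make_folds(ids: list[str], labels: dict[str, dict] | None, scheme: str,
               k: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign ids to cross-validation folds under one of five schemes.

    ``labels`` maps each id to its metadata dict (needs ``week`` for the
    time-based schemes, ``condition`` for condition stratification).
    """
    if scheme not in FOLD_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    ids = list(ids)
    if not ids:
        raise ValueError("no ids to split")
    if scheme not in ("validate_week8", "fold_by_week") and k < 2:
        raise ValueError("k-fold schemes require k >= 2")

    def _label(i, key):
        if labels is None or i not in labels or key not in labels[i]:
            raise ValueError(f"scheme {scheme} requires {key!r} label "
                             f"for id {i!r}")
        return labels[i][key]

    mapping: dict[str, int] = {}
    order = np.array(ids, dtype=object)
    if scheme == "random_kfold":
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, val_idx) in enumerate(kf.split(order)):
            for i in val_idx:
                mapping[order[i]] = f
    elif scheme in ("stratified_time", "stratified_condition"):
        key = "week" if scheme == "stratified_time" else "condition"
        y = np.array([str(_label(i, key)) for i in ids])
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, val_idx) in enumerate(skf.split(order, y)):
            for i in val_idx:
                mapping[order[i]] = f
    elif scheme == "fold_by_week":
        weeks = sorted({int(_label(i, "week")) for i in ids})
        if k != len(weeks):
            raise ValueError(f"fold_by_week requires k == number of weeks "
                             f"({len(weeks)}), got k={k}")
        fold_of = {wk: f for f, wk in enumerate(weeks)}
        for i in ids:
            mapping[i] = fold_of[int(_label(i, "week"))]
    else:  # validate_week8
        for i in ids:
            mapping[i] = 0 if int(_label(i, "week")) == 8 else -1
        k = 1
    return FoldAssignment(scheme=scheme, k=k, mapping=mapping, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _smooth_noise(rng: np.random.Generator, h: int, w: int,
                  sigma: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def render_synthetic_pair(spec: SyntheticSpec, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Render one stained image + pixel-exact mask obeying the spec ranges."""
    img, mask, _ = render_synthetic_scene(spec, rng)
    return img, mask


def render_synthetic_scene(spec: SyntheticSpec, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Render one image; also return the placed ellipses.

    Adipocytes are placed sequentially without overlap until a target
    fraction (drawn from ``adipose_fraction_range``) is reached; the whole
    image is re-drawn when the realized fraction or blob count falls
    outside the requested ranges.  The third return value lists each
    adipocyte as ``(cx, cy, a, b, theta)`` so the rasterized mask can be
    audited geometrically.
    """
    h, w = spec.height, spec.width
    lo, hi = spec.adipose_fraction_range
    pal = PALETTES[spec.stain]
    total = h * w
    for _ in range(25):                   # bounded whole-image retries
        target = rng.uniform(lo, hi)
        n_target = int(rng.integers(spec.n_blobs_range[0],
                                    spec.n_blobs_range[1] + 1))
        mask = np.zeros((h, w), dtype=bool)
        occupied = np.zeros((h, w), dtype=bool)
        membrane = np.zeros((h, w), dtype=bool)
        ellipses: list[tuple] = []
        placed = 0
        attempts = 0
        while placed < n_target and mask.mean() < target and attempts < 200:
            attempts += 1
            a = rng.uniform(*spec.blob_axis_range)
            b = rng.uniform(*spec.blob_axis_range)
            theta = rng.uniform(0, np.pi)
            m = spec.membrane_width
            cx = rng.uniform(a + m, w - 1 - a - m) if w - 1 > 2 * (a + m) else None
            cy = rng.uniform(b + m, h - 1 - b - m) if h - 1 > 2 * (b + m) else None
            if cx is None or cy is None:
                continue
            outer = _ellipse_mask(h, w, cx, cy, a + m, b + m, theta)
            if (outer & occupied).any():
                continue
            inner = _ellipse_mask(h, w, cx, cy, a, b, theta)
            if (mask.sum() + inner.sum()) / total > hi:
                continue
            mask |= inner
            membrane |= outer & ~inner
            occupied |= outer
            ellipses.append((cx, cy, a, b, theta))
            placed += 1
        frac = mask.mean()
        n_ok = spec.n_blobs_range[0] <= placed <= spec.n_blobs_range[1]
        if (lo <= frac <= hi) and (n_ok or (placed == 0 and lo == 0)):
            break
    else:
        raise GenerationError(
            f"could not satisfy adipose fraction in [{lo}, {hi}] with "
            f"{spec.n_blobs_range} blobs of axes {spec.blob_axis_range} "
            f"on a {h}x{w} canvas")

    img = np.empty((h, w, 3))
    blotch = np.clip(_smooth_noise(rng, h, w, sigma=min(h, w) / 8), -2, 2)
    blotch = (blotch - blotch.min()) / (np.ptp(blotch) + 1e-12)
    for c in range(3):
        base = (pal["background"][c] * (1 - 0.45 * blotch)
                + pal["blotch"][c] * 0.45 * blotch)
        img[..., c] = base
    img[membrane] = pal["membrane"]
    img[mask] = pal["adipocyte"]
    img += rng.normal(0, spec.noise_sd, img.shape)
    return np.clip(img, 0, 1), mask.astype(np.uint8), ellipses


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path
                               ) -> pd.DataFrame:
    """Write images, masks and a manifest CSV; returns the manifest.

    Weeks and conditions are assigned cyclically so every stratified fold
    scheme can be exercised on the result.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_images):
        pixels, mask = render_synthetic_pair(spec, rng)
        img_id = f"synth_{i:04d}"
        week = WEEKS[i % len(WEEKS)]
        condition = CONDITIONS[(i // len(WEEKS)) % len(CONDITIONS)]
        image_path = out_dir / "images" / f"{img_id}.png"
        mask_path = out_dir / "masks" / f"{img_id}.png"
        img = HistImage(pixels, id=img_id,
                        metadata={"week": week, "condition": condition,
                                  "stain": spec.stain,
                                  "reference_length": spec.reference_length})
        save_pair(img, mask, image_path, mask_path)
        rows.append({
            "id": img_id,
            "image_path": str(image_path),
            "mask_path": str(mask_path),
            "week": week,
            "condition": condition,
            "stain": spec.stain,
            "reference_length_um_per_px": spec.reference_length,
            "original_height": spec.height,
            "original_width": spec.width,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "image_path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")
    return df
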