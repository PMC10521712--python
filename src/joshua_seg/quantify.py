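"""Physical-area quantification of segmented adipose tissue.

Predicted masks live on downsampled images, so positive-pixel counts are
mapped back to full-resolution physical area via

    FA_full = FA_down * (IA_full / IA_down) * RL^2

where FA_down is the positive pixel count in the downsampled mask, IA_down
and IA_full are the downsampled and full-resolution image pixel areas, and
RL is the microscope reference length in microns per (full-resolution)
pixel.  The result is an area in square microns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .architectures import load_checkpoint, predict_probabilities
from .data_pipeline import HistImage, load_manifest, load_mask, load_image, resize_pair
from .seg_metrics import evaluate_masks

log = logging.getLogger(__name__)

AREA_COLUMNS = ["id", "week", "condition", "stain", "fa_down_px",
                "ia_down_px", "ia_full_px", "rl_um_per_px", "fa_full_um2"]

# Overlay palette: ground truth only, prediction only, agreement.
OVERLAY_TRUTH = (0, 0, 255)
OVERLAY_PRED = (255, 0, 0)
OVERLAY_AGREE = (144, 238, 144)


class MissingCalibrationError(ValueError):
    """Reference length is required to convert pixel counts to microns."""


@dataclass(frozen=True)
class AreaMeasurement:
    fa_down: int      # positive pixels in the downsampled mask
    ia_down: int      # downsampled image pixel area
    ia_full: int      # full-resolution image pixel area
    rl: float         # reference length, microns per pixel

    @property
    def fa_full(self) -> float:
        """Adipose area in square microns."""
        return self.fa_down * (self.ia_full / self.ia_down) * self.rl ** 2


def adipose_area(mask: np.ndarray, ia_full: int, rl: float) -> AreaMeasurement:
    """Measure the physical area of the positive class in a binary mask."""
    if rl is None or not np.isfinite(rl):
        raise MissingCalibrationError(
            "reference length (um/px) is missing; cannot compute area")
    if rl <= 0:
        raise ValueError(f"reference length must be positive, got {rl}")
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    return AreaMeasurement(fa_down=int(mask.sum()),
                           ia_down=int(mask.size),
                           ia_full=int(ia_full), rl=float(rl))


def aggregate_areas(table: pd.DataFrame, by: str = "week") -> pd.DataFrame:
    """Per-group n, median and quartiles (linear interpolation) of area.

    Groups are sorted numerically for weeks and lexically otherwise; the
    result is invariant to the row order of the input.
    """
    if by not in table.columns:
        raise ValueError(f"grouping column {by!r} not in table")
    rows = table.dropna(subset=[by, "fa_full_um2"])
    if rows.empty:
        raise ValueError("no measurements carry the grouping label")
    out = (rows.groupby(by)["fa_full_um2"]
           .agg(n="count",
                median="median",
                q25=lambda s: s.quantile(0.25),
                q75=lambda s: s.quantile(0.75))
           .reset_index())
    try:
        out = out.sort_values(by, key=lambda s: s.astype(float))
    except (TypeError, ValueError):
        out = out.sort_values(by)
    return out.reset_index(drop=True)


def make_overlay(image: np.ndarray, pred: np.ndarray,
                 truth: np.ndarray) -> np.ndarray:
    """Tricolour comparison image: truth-only blue, prediction-only red,
    agreement light green, background untouched."""
    out = np.round(np.asarray(image) * 255).astype(np.uint8).copy()
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    out[truth & ~pred] = OVERLAY_TRUTH
    out[pred & ~truth] = OVERLAY_PRED
    out[pred & truth] = OVERLAY_AGREE
    return out


def segment_directory(checkpoint: str | Path, source: str | Path,
                      out_dir: str | Path, threshold: float = 0.5,
                      target: tuple[int, int] = (256, 256)) -> pd.DataFrame:
    """Segment every image in a directory or manifest; write masks,
    overlays (when ground truth exists) and an area CSV.

    Images whose metadata lacks a reference length still get masks; their
    area cell is left empty with a logged warning.  Per-image failures are
    logged and skipped; the call fails only if every image fails.
    """
    model = load_checkpoint(checkpoint)
    div = 2 ** model.spec.depth
    if target[0] % div or target[1] % div:
        raise ValueError(f"target {target} not divisible by 2^{model.spec.depth}")
    out_dir = Path(out_dir)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    (out_dir / "overlays").mkdir(parents=True, exist_ok=True)

    source = Path(source)
    if source.is_dir():
        rows = [{"id": p.stem, "image_path": str(p)}
                for p in sorted(source.glob("*.png")) +
                sorted(source.glob("*.jpg")) + sorted(source.glob("*.tif"))]
        manifest = pd.DataFrame(rows)
    else:
        manifest = load_manifest(source)

    results = []
    failures = 0
    for row in manifest.to_dict("records"):
        try:
            img = load_image(row["image_path"], id=row["id"])
            h0, w0 = img.pixels.shape[:2]
            truth = None
            if row.get("mask_path") and not pd.isna(row["mask_path"]):
                truth = load_mask(row["mask_path"])
            small, truth_small = resize_pair(
                img, truth if truth is not None else
                np.zeros((h0, w0), np.uint8), target)
            probs = predict_probabilities(model, small.pixels)
            mask = (probs >= threshold).astype(np.uint8)
            Image.fromarray(mask * 255).save(
                out_dir / "masks" / f"{img.id}.png")
            if truth is not None:
                overlay = make_overlay(small.pixels, mask, truth_small)
                Image.fromarray(overlay).save(
                    out_dir / "overlays" / f"{img.id}.png")
            rl = row.get("reference_length_um_per_px")
            rec = {"id": img.id, "week": row.get("week"),
                   "condition": row.get("condition"),
                   "stain": row.get("stain"),
                   "fa_down_px": int(mask.sum()),
                   "ia_down_px": int(mask.size),
                   "ia_full_px": int(h0 * w0),
                   "rl_um_per_px": rl, "fa_full_um2": np.nan}
            if rl is not None and not pd.isna(rl):
                rec["fa_full_um2"] = adipose_area(mask, h0 * w0, rl).fa_full
            else:
                log.warning("image %s has no reference length; "
                            "area left empty", img.id)
            results.append(rec)
        except Exception:
            failures += 1
            log.exception("failed to segment %s", row.get("id"))
    if not results:
        raise RuntimeError(f"all {failures} images failed to segment")
    table = pd.DataFrame(results, columns=AREA_COLUMNS)
    table.to_csv(out_dir / "areas.csv", index=False)
    return table
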