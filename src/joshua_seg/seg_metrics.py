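"""Pixelwise confusion counts and binary segmentation metrics.

Seven quantities are reported for each (prediction, ground truth) pair:
accuracy, precision, recall (sensitivity), specificity, Dice/F1,
positive-class IOU (Jaccard) and overall IOU (the unweighted mean of the
positive-class and background-class IOUs).  When a metric's defining sets
are empty (e.g. precision with no predicted positives) it is 1 if the
prediction is vacuously correct — no positives exist and none were
predicted — and 0 otherwise; this rewards correct all-negative
predictions, matching common segmentation toolkits.

Per-image reports are macro-averaged: metrics are computed per image, then
averaged within a fold, then summarized as mean +/- sample SD across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity",
                "dice", "iou_positive", "iou_overall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    dice: float
    iou_positive: float
    iou_overall: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} mask must be strictly binary, "
                         f"found values {vals[:10]}")
    return mask.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel counts of the four outcomes of a binary comparison."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    # empty-set convention: a ratio whose defining set is empty is perfect
    return num / den if den else 1.0


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    """Derive the seven metrics from confusion counts.

    dice = 2*TP / (2*TP + FP + FN), equal to the F1 score;
    iou_positive = TP / (TP + FP + FN) (Jaccard index of the positive sets);
    iou_overall averages the positive and background class IOUs.
    """
    acc = _ratio(c.tp + c.tn, c.total)
    return MetricReport(
        accuracy=acc,
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        iou_positive=_ratio(c.tp, c.tp + c.fp + c.fn),
        iou_overall=0.5 * (_ratio(c.tp, c.tp + c.fp + c.fn)
                           + _ratio(c.tn, c.tn + c.fp + c.fn)),
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Convenience composition ``metrics_from_counts(confusion(...))``."""
    return metrics_from_counts(confusion(pred, truth))


def summarize(reports: list[MetricReport],
              groups: list | None = None) -> pd.DataFrame:
    """Mean +/- sample SD per metric, averaging within groups first.

    ``groups`` labels each report with its run (fold x seed); reports in
    the same group are averaged before the across-group mean and SD
    (ddof=1) are taken.  With no groups every report is its own run.
    """
    if not reports:
        raise ValueError("summarize requires at least one report")
    if groups is None:
        groups = list(range(len(reports)))
    if len(groups) != len(reports):
        raise ValueError("groups must label every report")
    df = pd.DataFrame([r.as_dict() for r in reports])
    df["__group__"] = groups
    per_run = df.groupby("__group__", sort=True).mean()
    out = pd.DataFrame({"mean": per_run.mean(), "sd": per_run.std(ddof=1)})
    if len(per_run) == 1:
        out["sd"] = 0.0
    out.index.name = "metric"
    return out


def reports_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-image rows (id/fold/seed/counts/metrics) into a table
    matching the on-disk CSV layout."""
    cols = (["id", "fold", "seed", "tp", "fp", "tn", "fn"]
            + list(METRIC_NAMES))
    return pd.DataFrame(rows, columns=cols)
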