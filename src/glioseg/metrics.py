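"""Evaluation metrics for binary tumor masks and tumor-presence scores.

Segmentation: Dice ``2|X∩Y|/(|X|+|Y|)``, Jaccard ``|X∩Y|/|X∪Y|`` and the 95th
percentile symmetric Hausdorff distance (HD95).  Classification: sensitivity
``TP/(TP+FN)``, specificity ``TN/(TN+FP)`` and AUC-ROC, which equals the
Mann-Whitney statistic ``P(score+ > score-) + 0.5 * P(tie)``.

Conventions (surfaced, never silently imputed):

* two empty masks -> Dice/Jaccard 1.0 with a warning;
* HD95 is undefined when either mask is empty; per-sample this raises, at
  dataset level the sample is skipped and counted in ``hd95_undefined``;
* the 95th percentile interpolates linearly between order statistics
  (numpy's default), which the brute-force test oracle matches;
* a boundary pixel is a positive pixel with at least one non-positive
  4-neighbour (pixels beyond the image edge count as non-positive).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionCounts", "MetricsReport", "dice_coefficient", "jaccard_index",
    "sensitivity_specificity", "auc_roc", "hd95", "confusion_from_predictions",
    "evaluate_dataset", "roc_curve_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def dice_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _as_bool(x), _as_bool(y)
    if x.shape != y.shape:
        raise ValueError("masks must share a shape")
    sx, sy = int(x.sum()), int(y.sum())
    if sx + sy == 0:
        warnings.warn("both masks empty: Dice defined as 1.0 by convention")
        return 1.0
    return 2.0 * int((x & y).sum()) / (sx + sy)


def jaccard_index(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _as_bool(x), _as_bool(y)
    if x.shape != y.shape:
        raise ValueError("masks must share a shape")
    union = int((x | y).sum())
    if union == 0:
        warnings.warn("both masks empty: Jaccard defined as 1.0 by convention")
        return 1.0
    return int((x & y).sum()) / union


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive ground truth")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative ground truth")
    return c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp)


def auc_roc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC-ROC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold) for export/plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    m = _as_bool(mask)
    interior = binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def hd95(x: np.ndarray, y: np.ndarray, spacing: float | tuple[float, float] = 1.0) -> float:
    """95th-percentile symmetric Hausdorff distance between mask boundaries."""
    bx, by = _boundary_points(x), _boundary_points(y)
    if len(bx) == 0 or len(by) == 0:
        raise UndefinedMetricError("HD95 undefined for an empty mask")
    sp = np.asarray(spacing if not np.isscalar(spacing) else (spacing, spacing), dtype=float)
    px, py = bx * sp, by * sp
    d_xy, _ = cKDTree(py).query(px)  # each X boundary point -> nearest Y point
    d_yx, _ = cKDTree(px).query(py)
    return float(max(np.percentile(d_xy, 95), np.percentile(d_yx, 95)))


def confusion_from_predictions(pred, truth) -> ConfusionCounts:
    """Pooled binary confusion counts over any aligned boolean collections."""
    p = _as_bool(np.asarray(pred)).ravel()
    t = _as_bool(np.asarray(truth)).ravel()
    if p.shape != t.shape:
        raise ValueError("predictions and truth must be aligned")
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()),
    )


@dataclass
class MetricsReport:
    dice: float
    jaccard: float
    sensitivity: float
    specificity: float
    auc_roc: float | None
    hd95: float | None
    confusion: ConfusionCounts
    n_samples: int
    hd95_undefined: int = 0
    accuracy: float | None = None
    extras: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = dataclasses.asdict(self.confusion)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_csv_row(self, path: str | Path) -> None:
        """One-row CSV with the segmentation metric columns."""
        pd.DataFrame([{
            "dice": self.dice, "jaccard": self.jaccard,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "hd95": self.hd95,
        }]).to_csv(path, index=False, lineterminator="\n")


def evaluate_dataset(predictions: list[np.ndarray], ground_truths: list[np.ndarray],
                     class_scores=None, class_labels=None,
                     spacing: float | tuple[float, float] = 1.0,
                     average: str = "macro") -> MetricsReport:
    """Dataset-level evaluation.

    Segmentation metrics are averaged per sample (macro, default) or pooled
    over all pixels (micro).  Dice/Jaccard for an empty prediction against a
    nonempty truth are 0; HD95-undefined samples are skipped and counted.
    Pixel-level sensitivity/specificity come from the pooled confusion matrix;
    AUC-ROC and accuracy are computed when per-sample class scores and labels
    are supplied.
    """
    if len(predictions) != len(ground_truths):
        raise ValueError("predictions and ground truths must be aligned")
    if len(predictions) == 0:
        raise ValueError("need at least one sample")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")

    dices, jaccards, hd_values, skipped = [], [], [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-empty convention already documented
        for p, t in zip(predictions, ground_truths):
            dices.append(dice_coefficient(p, t))
            jaccards.append(jaccard_index(p, t))
            try:
                hd_values.append(hd95(p, t, spacing=spacing))
            except UndefinedMetricError:
                skipped += 1

    pooled = confusion_from_predictions(np.concatenate([np.ravel(p) for p in predictions]),
                                        np.concatenate([np.ravel(t) for t in ground_truths]))
    if average == "micro":
        dice = 2 * pooled.tp / max(2 * pooled.tp + pooled.fp + pooled.fn, 1)
        jac = pooled.tp / max(pooled.tp + pooled.fp + pooled.fn, 1)
    else:
        dice, jac = float(np.mean(dices)), float(np.mean(jaccards))

    sens = pooled.tp / (pooled.tp + pooled.fn) if pooled.tp + pooled.fn else float("nan")
    spec = pooled.tn / (pooled.tn + pooled.fp) if pooled.tn + pooled.fp else float("nan")

    auc = None
    acc = None
    if class_scores is not None and class_labels is not None:
        labels = np.asarray(class_labels, dtype=int)
        scores = np.asarray(class_scores, dtype=np.float64)
        if len(np.unique(labels)) >= 2:
            auc = auc_roc(scores, labels)
        acc = float(np.mean((scores >= 0.5).astype(int) == labels))

    return MetricsReport(
        dice=dice, jaccard=jac, sensitivity=float(sens), specificity=float(spec),
        auc_roc=auc, hd95=float(np.mean(hd_values)) if hd_values else None,
        confusion=pooled, n_samples=len(predictions), hd95_undefined=skipped,
        accuracy=acc,
        extras={"per_sample_dice": [float(v) for v in dices]},
    )
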