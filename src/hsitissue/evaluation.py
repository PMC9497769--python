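"""Per-image classification metrics and image-level macro-averaging.

Each annotated image yields one confusion table per positive class, from
which sensitivity, specificity, F1 and the Matthews correlation
coefficient (MCC) are computed, plus a threshold-free ROC AUC from the
class scores.  Cohort-level numbers are macro-averaged at image level:
unweighted mean ± SD across images, reported per class — so images with
few annotated pixels count as much as large ones.

Two-class bookkeeping identities are asserted throughout: sensitivity of
one class equals specificity of the other, MCC is identical for both
classes, and a two-class softmax yields the same AUC for either class
taken as positive.

A metric whose denominator vanishes (e.g. specificity on an image with no
negative pixels) is reported as NaN ("undefined") and excluded from the
macro-average; exclusions are counted in the cohort report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import PredictionMap

METRICS = ("sensitivity", "specificity", "f1", "mcc", "roc_auc")
CLASSES = (1, 2)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts with respect to a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray,
              positive_class: int) -> ConfusionCounts:
    """Standard confusion counts over paired label vectors (values in {1, 2})."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {p.shape}")
    pos_t, pos_p = t == positive_class, p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, F1 and MCC from one confusion table.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    F1 = 2tp/(2tp+fp+fn); MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    A zero denominator yields NaN (excluded from macro-averages downstream).
    """
    if c.total == 0:
        raise ValueError("confusion table is empty")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan"),
    }


def roc_auc(true_labels: np.ndarray, positive_scores: np.ndarray,
            positive_class: int = 1) -> float:
    """Mann-Whitney ROC AUC: P(score_pos > score_neg), ties counted 1/2.

    Requires both classes among the true labels; returns NaN otherwise
    (single-class images are excluded from the macro-average).
    """
    t = np.asarray(true_labels)
    s = np.asarray(positive_scores, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError(f"labels and scores differ in length: {t.shape} vs {s.shape}")
    pos = t == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks over ties -> the 1/2 tie convention
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ImageMetrics:
    """Per-class metrics for one image plus its evaluated-pixel count."""

    animal_id: str
    per_class: dict[int, dict[str, float]]
    n_evaluated: int


def image_metrics(true_labels: np.ndarray, predicted_labels: np.ndarray,
                  class1_scores: np.ndarray | None = None,
                  animal_id: str = "unknown") -> ImageMetrics:
    """All metrics for one image, for both classes taken as positive.

    ``class1_scores`` are the softmax scores for class 1; class 2's AUC
    uses their complement (equal by construction for a two-class softmax —
    the mirror identity the cohort report relies on).
    """
    per_class: dict[int, dict[str, float]] = {}
    for cls in CLASSES:
        m = metrics_from_counts(confusion(true_labels, predicted_labels, cls))
        if class1_scores is not None:
            scores = class1_scores if cls == 1 else 1.0 - np.asarray(class1_scores)
            m["roc_auc"] = roc_auc(true_labels, scores, positive_class=cls)
        per_class[cls] = m
    return ImageMetrics(animal_id, per_class, int(len(np.asarray(true_labels))))


def metrics_from_prediction(mask_labels: np.ndarray, pm: PredictionMap) -> ImageMetrics:
    """Image metrics over the annotated, evaluated support of a prediction map."""
    support = (mask_labels > 0) & pm.evaluated()
    return image_metrics(mask_labels[support], pm.class_map[support],
                         pm.score_map[support][:, 0], pm.animal_id)


@dataclass
class CohortMetrics:
    """Image-level macro-averages: mean ± SD per class per metric."""

    mean: dict[int, dict[str, float]]
    sd: dict[int, dict[str, float]]
    n_images: int
    n_excluded: dict[int, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per class, 'mean ± sd' per metric."""
        rows = {}
        for cls in CLASSES:
            label = {1: "colon-mesocolon (resect)", 2: "retroperitoneum (preserve)"}[cls]
            rows[label] = {m: f"{self.mean[cls][m]:.2f} ± {self.sd[cls][m]:.2f}"
                           for m in METRICS if m in self.mean[cls]}
        return pd.DataFrame(rows).T


def macro_average(per_image: list[ImageMetrics], ddof: int = 0) -> CohortMetrics:
    """Unweighted mean and SD of each metric across images, per class.

    NaN (undefined) metric values are excluded from that metric's average
    and counted in ``n_excluded``.  SD is the population SD by default
    (``ddof=0``); pass ``ddof=1`` for the sample SD.
    """
    if not per_image:
        raise ValueError("no image metrics to average")
    mean: dict[int, dict[str, float]] = {c: {} for c in CLASSES}
    sd: dict[int, dict[str, float]] = {c: {} for c in CLASSES}
    excluded: dict[int, dict[str, int]] = {c: {} for c in CLASSES}
    for cls in CLASSES:
        metric_names = per_image[0].per_class[cls].keys()
        for m in metric_names:
            values = np.array([im.per_class[cls][m] for im in per_image])
            valid = values[~np.isnan(values)]
            excluded[cls][m] = int(np.isnan(values).sum())
            if len(valid):
                mean[cls][m] = float(valid.mean())
                sd[cls][m] = float(valid.std(ddof=ddof)) if len(valid) > ddof else 0.0
            else:
                mean[cls][m] = float("nan")
                sd[cls][m] = float("nan")
    return CohortMetrics(mean, sd, len(per_image), excluded)


ERROR_MAP_COLORS = {
    "unevaluated": (40, 40, 40),
    "correct": (255, 255, 255),
    "misclassified": (220, 30, 30),
}


def error_map(true_mask: np.ndarray, prediction: PredictionMap) -> np.ndarray:
    """RGB image flagging every misclassified pixel of the evaluated support."""
    true_mask = np.asarray(true_mask)
    if true_mask.shape != prediction.class_map.shape:
        raise ValueError(
            f"mask shape {true_mask.shape} != prediction shape "
            f"{prediction.class_map.shape}")
    h, w = true_mask.shape
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[...] = ERROR_MAP_COLORS["unevaluated"]
    evaluated = prediction.evaluated() & (true_mask > 0)
    correct = evaluated & (prediction.class_map == true_mask)
    rgb[evaluated] = ERROR_MAP_COLORS["misclassified"]
    rgb[correct] = ERROR_MAP_COLORS["correct"]
    return rgb


def misclassified_count(true_mask: np.ndarray, prediction: PredictionMap) -> int:
    evaluated = prediction.evaluated() & (np.asarray(true_mask) > 0)
    return int(np.sum(evaluated & (prediction.class_map != np.asarray(true_mask))))
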