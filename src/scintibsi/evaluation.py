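"""Performance metrics: Dice overlap, per-lesion sensitivity, false-positive
pixel/region counts and BSI agreement.

Lesion-level quantities use 8-connectivity: a true metastatic lesion is a
connected component of the truth raster, and it counts as detected when at
least one of its pixels is predicted metastatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .labels import (ANTERIOR_CLASSES, METASTATIC, POSTERIOR_CLASSES,
                     SkeletonLabelMap)

__all__ = ["EvalMetrics", "dice_score", "lesion_sensitivity",
           "false_positive_stats", "bsi_correlation", "per_bone_dice"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class EvalMetrics:
    per_bone_dice: dict
    lesion_sensitivity: float
    fp_pixels: int
    fp_regions: int
    misclassified_pixels: int
    bsi_correlation: float | None = None

    def to_dict(self) -> dict:
        return {"per_bone_dice": self.per_bone_dice,
                "lesion_sensitivity": self.lesion_sensitivity,
                "fp_pixels": self.fp_pixels, "fp_regions": self.fp_regions,
                "misclassified_pixels": self.misclassified_pixels,
                "bsi_correlation": self.bsi_correlation}


def dice_score(segmented: np.ndarray, truth: np.ndarray) -> float:
    """``2|A∩B| / (|A|+|B|)``; defined as 1 when both regions are empty so
    per-bone averages stay well-defined for absent bones."""
    a = np.asarray(segmented).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def per_bone_dice(predicted: SkeletonLabelMap, truth: SkeletonLabelMap
                  ) -> dict[str, dict[str, float]]:
    """Dice per bone class, per view."""
    out: dict[str, dict[str, float]] = {}
    for view, classes in (("anterior", ANTERIOR_CLASSES),
                          ("posterior", POSTERIOR_CLASSES)):
        pred = getattr(predicted, view)
        true = getattr(truth, view)
        out[view] = {name: dice_score(pred == idx, true == idx)
                     for idx, name in enumerate(classes) if idx > 0}
    return out


def lesion_sensitivity(predicted: np.ndarray, truth: np.ndarray
                       ) -> tuple[float, list[dict]]:
    """Fraction of 8-connected true metastatic components overlapped by at
    least one predicted metastatic pixel, plus per-lesion detail."""
    pred_met = np.asarray(predicted) == METASTATIC
    comp, n = ndimage.label(np.asarray(truth) == METASTATIC, structure=_EIGHT)
    if n == 0:
        raise ValueError("no true metastatic lesions in the truth raster")
    detail = []
    detected = 0
    for i in range(1, n + 1):
        mask = comp == i
        hit = bool((pred_met & mask).any())
        detected += hit
        detail.append({"lesion": i, "area_px": int(mask.sum()), "detected": hit})
    return detected / n, detail


def false_positive_stats(predicted: np.ndarray, truth: np.ndarray
                         ) -> tuple[int, int, int]:
    """``(fp_pixels, fp_regions, misclassified_pixels)`` for the metastatic
    class; regions are 8-connected components of the false-positive set and
    misclassified pixels count the union of false positives and negatives."""
    pred = np.asarray(predicted) == METASTATIC
    true = np.asarray(truth) == METASTATIC
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    fp = pred & ~true
    fn = true & ~pred
    _, n_regions = ndimage.label(fp, structure=_EIGHT)
    return int(fp.sum()), int(n_regions), int((fp | fn).sum())


def bsi_correlation(measured, truth) -> float:
    """Pearson correlation between measured and true BSI series."""
    x = np.asarray(measured, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length series of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a BSI series")
    return float(pearsonr(x, y).statistic)
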