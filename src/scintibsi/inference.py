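"""From trained-network logits to hard labels.

Skeleton: per-pixel argmax over softmax probabilities (ties break toward
the lower class index, i.e. background first). Hot spots: a three-way
decision rule — metastatic wherever the metastatic probability clears a
threshold, otherwise non-malignant where it beats "others", otherwise
others. The threshold is calibrated so the per-lesion sensitivity on a
calibration fold reaches a target (0.9 in the reference protocol): the
largest threshold at which the required fraction of true lesions still
contains at least one metastatic-labeled pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .labels import (METASTATIC, NON_MALIGNANT, OTHERS, SkeletonLabelMap)
from .losses import softmax
from .networks import DualViewLogits

__all__ = ["HotspotField", "Threshold", "segment_skeleton",
           "classify_hotspots", "calibrate_threshold"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class HotspotField:
    """Per-pixel 3-class probabilities ``(3, H, W)`` in the label order
    (others, metastatic, non_malignant)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) probabilities, got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("probabilities must sum to 1 per pixel")

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "HotspotField":
        return cls(probs=softmax(np.asarray(logits, dtype=np.float64), axis=0))

    @property
    def p_others(self) -> np.ndarray:
        return self.probs[OTHERS]

    @property
    def p_meta(self) -> np.ndarray:
        return self.probs[METASTATIC]

    @property
    def p_nonmal(self) -> np.ndarray:
        return self.probs[NON_MALIGNANT]


@dataclass
class Threshold:
    """Calibrated metastatic-probability threshold."""

    th: float
    calibration_target: float = 0.9
    calibration_set: str = ""
    achieved_sensitivity: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.th <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


def segment_skeleton(logits: DualViewLogits) -> SkeletonLabelMap:
    """Per-pixel argmax label per view (softmax is monotone, so argmax over
    probabilities equals argmax over logits; ties go to the lowest index)."""
    ant = np.argmax(softmax(logits.anterior, axis=0), axis=0).astype(np.uint8)
    post = np.argmax(softmax(logits.posterior, axis=0), axis=0).astype(np.uint8)
    return SkeletonLabelMap(anterior=ant, posterior=post)


def classify_hotspots(field: HotspotField, th: Threshold | float) -> np.ndarray:
    """Three-way per-pixel rule, evaluated in order: metastatic if
    ``p_meta >= th``; else non-malignant if ``p_nonmal >= p_others``; else
    others."""
    t = th.th if isinstance(th, Threshold) else float(th)
    labels = np.full(field.p_meta.shape, OTHERS, dtype=np.uint8)
    nonmal = field.p_nonmal >= field.p_others
    labels[nonmal] = NON_MALIGNANT
    labels[field.p_meta >= t] = METASTATIC
    return labels


def _lesion_max_probs(fields: list[HotspotField], truths: list[np.ndarray]
                      ) -> np.ndarray:
    """Max metastatic probability inside each 8-connected true lesion."""
    maxima = []
    for f, truth in zip(fields, truths):
        comp, n = ndimage.label(np.asarray(truth) == METASTATIC, structure=_EIGHT)
        for i in range(1, n + 1):
            maxima.append(float(f.p_meta[comp == i].max()))
    return np.asarray(maxima)


def calibrate_threshold(fields: list[HotspotField], truths: list[np.ndarray],
                        target_sensitivity: float = 0.9,
                        calibration_set: str = "validation") -> Threshold:
    """Choose the largest threshold whose per-lesion sensitivity on the
    calibration set is at least ``target_sensitivity``.

    A lesion counts as detected when at least one of its pixels has
    ``p_meta >= th``, so per-lesion maxima are sufficient statistics and
    the sweep runs over their sorted values.
    """
    maxima = _lesion_max_probs(fields, truths)
    L = len(maxima)
    if L == 0:
        raise ValueError("no metastatic lesions in the calibration set")
    order = np.sort(maxima)[::-1]
    need = int(np.ceil(target_sensitivity * L))
    th = float(order[need - 1])  # need-th largest: exactly >= `need` detections
    achieved = float((maxima >= th).sum() / L)
    return Threshold(th=th, calibration_target=target_sensitivity,
                     calibration_set=calibration_set,
                     achieved_sensitivity=achieved)
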