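"""Training objectives for the two segmentation tasks.

Two losses are used: the generalized Dice loss (GDL) for multi-bone
skeleton segmentation, where class pixel counts differ by orders of
magnitude, and a class-weighted softmax cross entropy (WSCE) for the
three-class hot-spot task. Both operate on ``(C, N)`` fields: C classes
by N pixels; images are flattened before scoring.

Gradients with respect to the pre-softmax logits are provided in closed
form (``*_grad_logits``) so the network tape never needs scalar ops.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["softmax", "generalized_dice_loss", "generalized_dice_grad_logits",
           "class_weights", "weighted_softmax_cross_entropy",
           "weighted_softmax_cross_entropy_grad_logits", "dsv_loss",
           "dsv_grad_logits", "PROB_FLOOR", "DEFAULT_GDL_EPS"]

#: floor applied inside log() — the cross entropy is undefined at p = 0
PROB_FLOOR = 1e-12
#: stabilizer added to the Dice numerator and denominator per class
DEFAULT_GDL_EPS = 1e-3


def softmax(y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Softmax along ``axis``, stabilized by max subtraction (value-identical)."""
    y = np.asarray(y, dtype=np.float64)
    z = y - y.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_cn(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 2:
        raise ValueError(f"expected matching (C, N) fields, got {p.shape} vs {t.shape}")
    return p, t


def generalized_dice_loss(p: np.ndarray, t: np.ndarray,
                          eps: float = DEFAULT_GDL_EPS) -> float:
    """Generalized Dice loss ``1 - (2/C) * sum_c (sum_n p*t + eps)/(sum_n p + sum_n t + eps)``.

    ``p`` holds per-class probabilities, ``t`` the one-hot truth, both
    ``(C, N)``. ``eps`` prevents division by zero for empty classes.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    p, t = _check_cn(p, t)
    C = p.shape[0]
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    return float(1.0 - (2.0 / C) * ((inter + eps) / (denom + eps)).sum())


def generalized_dice_grad_logits(y: np.ndarray, t: np.ndarray,
                                 eps: float = DEFAULT_GDL_EPS) -> np.ndarray:
    """d GDL / d logits, chained analytically through the softmax."""
    p = softmax(y, axis=0)
    p, t = _check_cn(p, t)
    C = p.shape[0]
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    # dL/dp_cn = -(2/C) * [ t_cn/(denom+eps) - (inter+eps)/(denom+eps)^2 ]
    g = -(2.0 / C) * (t / (denom + eps)[:, None]
                      - ((inter + eps) / (denom + eps) ** 2)[:, None])
    # softmax Jacobian: dL/dy_kn = p_kn * (g_kn - sum_c p_cn g_cn)
    return p * (g - (p * g).sum(axis=0, keepdims=True))


def class_weights(t: np.ndarray) -> np.ndarray:
    """Per-class weights ``w_c = (N - sum_n t_cn) / N``.

    Rare classes approach weight 1, a class covering every pixel gets 0,
    counteracting the pixel-count imbalance between lesions and background.
    """
    t = np.asarray(t, dtype=np.float64)
    N = t.shape[1]
    if N == 0:
        raise ValueError("empty target field")
    return (N - t.sum(axis=1)) / N


def weighted_softmax_cross_entropy(p: np.ndarray, t: np.ndarray,
                                   w: np.ndarray | None = None) -> float:
    """Class-weighted cross entropy ``-(1/N) sum_n sum_c w_c t_cn ln p_cn``.

    ``w`` defaults to :func:`class_weights` of ``t``. True-class
    probabilities are floored at ``PROB_FLOOR`` (with a warning) so the
    loss stays finite.
    """
    p, t = _check_cn(p, t)
    if w is None:
        w = class_weights(t)
    w = np.asarray(w, dtype=np.float64)
    N = p.shape[1]
    if np.any((p < PROB_FLOOR) & (t > 0)):
        warnings.warn("true-class probability at the floor; loss clamped",
                      RuntimeWarning, stacklevel=2)
    logp = np.log(np.maximum(p, PROB_FLOOR))
    return float(-(w[:, None] * t * logp).sum() / N)


def weighted_softmax_cross_entropy_grad_logits(y: np.ndarray, t: np.ndarray,
                                               w: np.ndarray | None = None
                                               ) -> np.ndarray:
    """d WSCE / d logits: ``(1/N) * (p * w_true - w ⊙ t)`` with one-hot t."""
    t = np.asarray(t, dtype=np.float64)
    if w is None:
        w = class_weights(t)
    w = np.asarray(w, dtype=np.float64)
    p = softmax(y, axis=0)
    N = t.shape[1]
    w_true = (w[:, None] * t).sum(axis=0, keepdims=True)  # weight of each pixel's class
    return (p * w_true - w[:, None] * t) / N


def dsv_loss(outputs: list[np.ndarray], t: np.ndarray,
             eps: float = DEFAULT_GDL_EPS) -> float:
    """Deep-supervision objective: sum of generalized Dice losses over the
    six supervised logit fields (two output heads + four side taps), each
    scored against the same full-resolution target."""
    if len(outputs) != 6:
        raise ValueError(f"deep supervision expects 6 supervised outputs, got {len(outputs)}")
    return float(sum(generalized_dice_loss(softmax(y, axis=0), t, eps)
                     for y in outputs))


def dsv_grad_logits(outputs: list[np.ndarray], t: np.ndarray,
                    eps: float = DEFAULT_GDL_EPS) -> list[np.ndarray]:
    if len(outputs) != 6:
        raise ValueError(f"deep supervision expects 6 supervised outputs, got {len(outputs)}")
    return [generalized_dice_grad_logits(y, t, eps) for y in outputs]
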