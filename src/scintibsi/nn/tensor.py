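"""Minimal reverse-mode autodiff on numpy arrays.

Only the handful of operations a butterfly-type fully convolutional
network needs are provided: 2-D convolution (stride 1 or 2), a 2x2
stride-2 transposed convolution, batch normalization, ReLU, channel
concatenation, elementwise addition and nearest-neighbour upsampling.
Loss functions feed their analytic logit gradient into ``backward``
directly, so no scalar-reduction ops are required.

All arrays are ``(B, C, H, W)`` in the module-wide ``DTYPE`` (float32 by
default; switchable to float64 for finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "deconv2x2", "batch_norm", "relu", "concat",
           "add", "upsample_nearest", "gather_heads", "set_default_dtype",
           "get_default_dtype"]

#: dtype of all tape arrays; float32 is the training default, float64 is
#: used by the finite-difference gradient checks
DTYPE = np.dtype(np.float32)


def set_default_dtype(dt) -> None:
    global DTYPE
    DTYPE = np.dtype(dt)


def get_default_dtype():
    return DTYPE


class Tensor:
    """An ndarray plus the tape machinery for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate ``grad`` (dL/dself) through the recorded tape."""
        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor{self.shape}{' ' + self.name if self.name else ''}"


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; ``w`` is ``(Cout, Cin, k, k)``, ``b`` is ``(Cout,)``.

    im2col + one GEMM in each direction; the column buffer is kept for the
    weight gradient.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cin2, k, k2 = w.data.shape
    assert Cin == Cin2 and k == k2
    s = stride
    Ho = (H + 2 * pad - k) // s + 1
    Wo = (W + 2 * pad - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    # channels-last im2col built from k*k cheap slice copies
    xpt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (B, Hp, Wp, Cin)
    cols6 = np.empty((B, Ho, Wo, k, k, Cin), dtype=DTYPE)
    for ki in range(k):
        for kj in range(k):
            cols6[:, :, :, ki, kj, :] = xpt[:, ki:ki + s * Ho:s, kj:kj + s * Wo:s, :]
    cols = cols6.reshape(B * Ho * Wo, k * k * Cin)
    wmat = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(Cout, k * k * Cin)
    y = (cols @ wmat.T).reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(y) + b.data[None, :, None, None]

    def backward(dy: np.ndarray) -> None:
        if b.requires_grad:
            b._accumulate(dy.sum(axis=(0, 2, 3)))
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)
                                      ).reshape(B * Ho * Wo, Cout)
        if w.requires_grad:
            dw = (dy_mat.T @ cols).reshape(Cout, k, k, Cin).transpose(0, 3, 1, 2)
            w._accumulate(np.ascontiguousarray(dw))
        if x.requires_grad or x._backward is not None or x._parents:
            dcols = (dy_mat @ wmat).reshape(B, Ho, Wo, k, k, Cin)
            dxpt = np.zeros_like(xpt)
            for ki in range(k):
                for kj in range(k):
                    dxpt[:, ki:ki + s * Ho:s, kj:kj + s * Wo:s, :] += \
                        dcols[:, :, :, ki, kj, :]
            dxp = dxpt.transpose(0, 3, 1, 2)
            dx = dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp
            x._accumulate(np.ascontiguousarray(dx))

    return _make(y, (x, w, b), backward)


def deconv2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (no overlap).

    ``w`` is ``(Cin, Cout, 2, 2)``; output is ``(B, Cout, 2H, 2W)``. Each
    input pixel expands into a 2x2 output block, i.e. a per-pixel linear map.
    """
    B, Cin, H, W = x.data.shape
    Cin2, Cout, _, _ = w.data.shape
    assert Cin == Cin2
    # (B,Cin,H,W) x (Cin,Cout,2,2) -> (B,H,W,Cout,2,2)
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    y = t.transpose(0, 3, 1, 4, 2, 5).reshape(B, Cout, 2 * H, 2 * W)
    y = y + b.data[None, :, None, None]

    def backward(dy: np.ndarray) -> None:
        if b.requires_grad:
            b._accumulate(dy.sum(axis=(0, 2, 3)))
        d = dy.reshape(B, Cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # B,H,W,Cout,2,2
        if w.requires_grad:
            dw = np.tensordot(x.data, d, axes=([0, 2, 3], [0, 1, 2]))  # Cin,Cout,2,2
            w._accumulate(dw)
        dx = np.tensordot(d, w.data, axes=([3, 4, 5], [1, 2, 3]))  # B,H,W,Cin
        x._accumulate(dx.transpose(0, 3, 1, 2))

    return _make(y, (x, w, b), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization. Running stats are updated in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(dy: np.ndarray) -> None:
        if beta.requires_grad:
            beta._accumulate(dy.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((dy * xhat).sum(axis=(0, 2, 3)))
        g = dy * gamma.data[None, :, None, None]
        if training:
            m = dy.shape[0] * dy.shape[2] * dy.shape[3]
            gs = g.sum(axis=(0, 2, 3))[None, :, None, None]
            gxs = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = (inv_std[None, :, None, None] / m) * (m * g - gs - xhat * gxs)
        else:
            dx = g * inv_std[None, :, None, None]
        x._accumulate(dx)

    return _make(y, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def backward(dy: np.ndarray) -> None:
        x._accumulate(dy * mask)

    return _make(y, (x,), backward)


def concat(xs: list[Tensor], axis: int = 1) -> Tensor:
    y = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.data.shape[axis] for t in xs]
    splits = np.cumsum(sizes)[:-1]

    def backward(dy: np.ndarray) -> None:
        for t, g in zip(xs, np.split(dy, splits, axis=axis)):
            t._accumulate(g)

    return _make(y, tuple(xs), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(dy: np.ndarray) -> None:
        a._accumulate(dy)
        b._accumulate(dy)

    return _make(y, (a, b), backward)


def gather_heads(pairs: list[tuple[Tensor, np.ndarray]]) -> Tensor:
    """Combine several output heads with fixed upstream gradients into one
    scalar root, so a multi-head loss needs a single ``backward(1.0)`` call
    (repeated ``backward`` calls on one graph would double-count shared
    subgraphs)."""
    def backward(dy: np.ndarray) -> None:
        for t, g in pairs:
            t._accumulate(float(dy) * np.asarray(g, dtype=DTYPE))

    return _make(0.0, tuple(t for t, _ in pairs), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    y = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

    def backward(dy: np.ndarray) -> None:
        B, C, H, W = x.data.shape
        dx = dy.reshape(B, C, H, f, W, f).sum(axis=(3, 5))
        x._accumulate(dx)

    return _make(y, (x,), backward)
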