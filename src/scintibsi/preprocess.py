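"""Geometric and intensity normalization shared by both segmentation tasks.

The pipeline order mirrors acquisition practice for paired whole-body
scintigrams: the posterior view (acquired mirrored) is flipped and rigidly
aligned to the anterior view; both views are spatially standardized so the
body axis is vertical and the head-to-toe extent corresponds to 2000 mm at
the configured output spacing; grey values are normalized with a golden-
ratio log transform; and for hot-spot extraction the images are tiled into
64x64 patches on a 32-pixel grid restricted to the body mask.

Raster convention: row-major, origin top-left, (row, col) indexing, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.morphology import disk

from .labels import OTHERS

__all__ = ["ScintigramPair", "StandardizationTransform", "PatchSet",
           "GOLDEN_RATIO", "flip_and_align", "spatially_standardize",
           "normalize_grey", "body_mask", "tile_patches", "assemble_patches",
           "invert_standardization", "central_crop", "uncrop_labels",
           "PreprocessError"]

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0

PATCH_SIZE = 64
PATCH_STRIDE = 32

#: default output pixel spacing; 2000 mm head-to-toe is then 250 px at desk
#: raster sizes (the full-scale profile uses 2.0 mm/px -> 1000 px)
DEFAULT_SPACING_MM = 8.0


class PreprocessError(ValueError):
    """Raised for degenerate inputs (empty masks, flat images, bad shapes)."""


@dataclass
class ScintigramPair:
    """Paired anterior/posterior count rasters with geometry metadata."""

    anterior: np.ndarray
    posterior: np.ndarray
    pixel_spacing_mm: float = DEFAULT_SPACING_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.anterior = np.asarray(self.anterior)
        self.posterior = np.asarray(self.posterior)
        if np.any(self.anterior < 0) or np.any(self.posterior < 0):
            raise ValueError("count rasters must be non-negative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.anterior.shape


@dataclass
class StandardizationTransform:
    """Affine map between raster frames, as a 3x3 homogeneous matrix on
    ``(row, col, 1)`` coordinates: ``output = matrix @ input``.

    ``rotation_rad``, ``scale`` and ``translation_px`` describe the rigid
    components for reporting; ``flip`` records whether a horizontal mirror
    is folded into the matrix (posterior alignment).
    """

    matrix: np.ndarray
    rotation_rad: float = 0.0
    scale: float = 1.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    flip: bool = False

    @property
    def is_invertible(self) -> bool:
        return abs(np.linalg.det(self.matrix[:2, :2])) > 1e-12

    @classmethod
    def identity(cls) -> "StandardizationTransform":
        return cls(matrix=np.eye(3))

    @classmethod
    def from_components(cls, rotation_rad: float = 0.0, scale: float = 1.0,
                        translation_px: tuple[float, float] = (0.0, 0.0),
                        center_px: tuple[float, float] = (0.0, 0.0),
                        ) -> "StandardizationTransform":
        """Rotation then isotropic scaling about ``center_px``, then translation."""
        cr, cc = center_px
        tr, tc = translation_px
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        S = np.diag([scale, scale, 1.0])
        to_c = np.array([[1, 0, -cr], [0, 1, -cc], [0, 0, 1.0]])
        from_c = np.array([[1, 0, cr], [0, 1, cc], [0, 0, 1.0]])
        T = np.array([[1, 0, tr], [0, 1, tc], [0, 0, 1.0]])
        return cls(matrix=T @ from_c @ S @ R @ to_c, rotation_rad=rotation_rad,
                   scale=scale, translation_px=(tr, tc))

    @classmethod
    def horizontal_flip(cls, width: int) -> "StandardizationTransform":
        m = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, width - 1.0], [0.0, 0.0, 1.0]])
        return cls(matrix=m, flip=True)

    def compose(self, inner: "StandardizationTransform") -> "StandardizationTransform":
        """Transform applying ``inner`` first, then ``self``."""
        return StandardizationTransform(
            matrix=self.matrix @ inner.matrix,
            rotation_rad=self.rotation_rad + inner.rotation_rad,
            scale=self.scale * inner.scale,
            translation_px=tuple(np.add(self.translation_px, inner.translation_px)),
            flip=self.flip != inner.flip)

    def inverse(self) -> "StandardizationTransform":
        if not self.is_invertible:
            raise PreprocessError("transform is not invertible")
        return StandardizationTransform(
            matrix=np.linalg.inv(self.matrix), rotation_rad=-self.rotation_rad,
            scale=1.0 / self.scale,
            translation_px=tuple(-np.asarray(self.translation_px)),
            flip=self.flip)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        """Map ``(M, 2)`` (row, col) points input -> output frame."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        h = np.hstack([pts, np.ones((pts.shape[0], 1))])
        return (self.matrix @ h.T).T[:, :2]

    def warp_image(self, image: np.ndarray, output_shape: tuple[int, int],
                   order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Resample ``image`` into the output frame of this transform."""
        inv = np.linalg.inv(self.matrix)
        return ndimage.affine_transform(
            np.asarray(image, dtype=np.float64), inv[:2, :2], offset=inv[:2, 2],
            output_shape=output_shape, order=order, cval=cval,
            mode="constant", prefilter=order > 1)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "rotation_rad": self.rotation_rad,
                "scale": self.scale, "translation_px": list(self.translation_px),
                "flip": self.flip}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationTransform":
        return cls(matrix=np.asarray(d["matrix"]), rotation_rad=d["rotation_rad"],
                   scale=d["scale"], translation_px=tuple(d["translation_px"]),
                   flip=d["flip"])


@dataclass
class PatchSet:
    """Paired 64x64 anterior/posterior patches on the stride-32 grid."""

    anterior: np.ndarray            # (P, 64, 64)
    posterior: np.ndarray           # (P, 64, 64)
    origins: np.ndarray             # (P, 2) (row, col) in the standardized frame
    stride_px: int = PATCH_STRIDE
    image_shape: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if np.any(np.asarray(self.origins) % self.stride_px):
            raise ValueError("patch origins must lie on the stride grid")

    def __len__(self) -> int:
        return len(self.origins)


def body_mask(raster: np.ndarray) -> np.ndarray:
    """Binary body mask: 3x3 median filter, threshold at counts >= 4, then
    morphological opening and closing with a radius-2 disk."""
    med = ndimage.median_filter(np.asarray(raster, dtype=np.float64), size=3)
    mask = med >= 4
    selem = disk(2).astype(bool)
    # erosion pads with 1 and dilation with 0, so a mask touching the
    # raster border is not eaten away (an all-ones mask stays all ones)
    mask = ndimage.binary_dilation(
        ndimage.binary_erosion(mask, selem, border_value=1), selem)  # opening
    mask = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, selem), selem, border_value=1)  # closing
    return mask.astype(np.uint8)


def flip_and_align(pair: ScintigramPair, search_radius: int = 32
                   ) -> tuple[ScintigramPair, StandardizationTransform]:
    """Mirror the posterior view horizontally and rigidly translate it to
    maximize body-mask overlap with the anterior view.

    Returns the aligned pair and the transform that maps acquired posterior
    coordinates into the aligned (anterior) frame.
    """
    H, W = pair.anterior.shape
    mirrored = np.fliplr(pair.posterior)
    m_ant = body_mask(pair.anterior).astype(np.float64)
    m_post = body_mask(mirrored).astype(np.float64)
    if not m_ant.any() or not m_post.any():
        raise PreprocessError("empty body mask; cannot align views")
    # overlap(shift) for every integer shift at once via cross-correlation
    corr = signal.correlate(m_ant, m_post, mode="full", method="fft")
    center = (H - 1, W - 1)
    r = int(search_radius)
    win = corr[center[0] - r:center[0] + r + 1, center[1] - r:center[1] + r + 1]
    idx = np.unravel_index(np.argmax(win), win.shape)
    shift = (idx[0] - r, idx[1] - r)  # shift applied to the mirrored posterior
    aligned = ndimage.shift(np.asarray(mirrored, dtype=np.float64), shift,
                            order=0, cval=0.0)
    t = StandardizationTransform(
        matrix=np.array([[1.0, 0.0, shift[0]], [0.0, 1.0, shift[1]], [0.0, 0.0, 1.0]])
        @ StandardizationTransform.horizontal_flip(W).matrix,
        translation_px=(float(shift[0]), float(shift[1])), flip=True)
    out = ScintigramPair(anterior=pair.anterior.copy(), posterior=aligned,
                         pixel_spacing_mm=pair.pixel_spacing_mm,
                         meta=dict(pair.meta))
    return out, t


def _principal_axis_angle(mask: np.ndarray) -> tuple[float, np.ndarray]:
    rows, cols = np.nonzero(mask)
    if len(rows) < 16:
        raise PreprocessError("body mask too small for axis estimation")
    pts = np.stack([rows, cols]).astype(np.float64)
    center = pts.mean(axis=1)
    cov = np.cov(pts - center[:, None])
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-9 or (evals[0] / evals[1]) > 0.98:
        raise PreprocessError("degenerate body mask: principal axis undefined")
    v = evecs[:, 1]  # dominant axis (row, col)
    if v[0] < 0:
        v = -v
    # angle of the body axis away from the vertical (row) direction
    return float(np.arctan2(v[1], v[0])), center


def spatially_standardize(pair: ScintigramPair,
                          output_spacing_mm: float = DEFAULT_SPACING_MM,
                          output_shape: tuple[int, int] | None = None,
                          body_extent_mm: float = 2000.0,
                          ) -> tuple[ScintigramPair, StandardizationTransform]:
    """Rotate/scale/translate both views so the body axis is vertical, the
    head-to-toe mask extent spans ``body_extent_mm`` at the output spacing,
    and the body centroid is horizontally centered."""
    out_shape = output_shape or pair.anterior.shape
    mask = (body_mask(pair.anterior) | body_mask(pair.posterior)).astype(np.uint8)
    if not mask.any():
        raise PreprocessError("empty body mask; cannot standardize")
    angle, center = _principal_axis_angle(mask)
    rot = StandardizationTransform.from_components(rotation_rad=-angle,
                                                   center_px=tuple(center))
    rot_mask = rot.warp_image(mask, mask.shape, order=0) > 0.5
    rows = np.nonzero(rot_mask.any(axis=1))[0]
    extent = float(rows[-1] - rows[0] + 1)
    target_extent = body_extent_mm / output_spacing_mm
    s = target_extent / extent
    # after scaling about the origin, place the extent center at the output
    # center row and the mask centroid at the output center column
    cols = np.nonzero(rot_mask)[1]
    mid_row = 0.5 * (rows[0] + rows[-1] + 1)
    mid_col = float(cols.mean())
    scale_t = StandardizationTransform.from_components(scale=s)
    tr = (out_shape[0] / 2.0 - s * mid_row, out_shape[1] / 2.0 - s * mid_col)
    shift_t = StandardizationTransform.from_components(translation_px=tr)
    t = shift_t.compose(scale_t).compose(rot)
    t.rotation_rad, t.scale = -angle, s
    std = ScintigramPair(
        anterior=np.maximum(t.warp_image(pair.anterior, out_shape, order=1), 0.0),
        posterior=np.maximum(t.warp_image(pair.posterior, out_shape, order=1), 0.0),
        pixel_spacing_mm=output_spacing_mm, meta=dict(pair.meta))
    return std, t


def normalize_grey(raster: np.ndarray, mask: np.ndarray | None = None
                   ) -> np.ndarray:
    """Golden-ratio log grey normalization.

    ``out = ln(phi * (I - I98) / (I10 - I98) + 1)`` where ``I > I98`` and 0
    elsewhere; ``I10``/``I98`` are the upper 10th / 98th percentiles (the
    intensity exceeded by 10% / 98% of body pixels), computed over the body
    mask so background zeros do not dominate.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if mask is None:
        mask = body_mask(raster)
    vals = raster[np.asarray(mask) > 0]
    if vals.size == 0:
        vals = raster.ravel()
    i10 = float(np.percentile(vals, 90.0))  # exceeded by 10% of pixels
    i98 = float(np.percentile(vals, 2.0))   # exceeded by 98% of pixels
    if i10 <= i98:
        raise PreprocessError("flat image: normalization percentiles coincide")
    out = np.zeros_like(raster)
    above = raster > i98
    out[above] = np.log(GOLDEN_RATIO * (raster[above] - i98) / (i10 - i98) + 1.0)
    return out


def tile_patches(pair: ScintigramPair, mask: np.ndarray) -> PatchSet:
    """All grid-aligned 64x64 paired patches (stride 32) whose footprint
    contains at least one body-mask pixel."""
    H, W = pair.anterior.shape
    if H < PATCH_SIZE or W < PATCH_SIZE:
        raise PreprocessError(f"raster {H}x{W} smaller than patch size {PATCH_SIZE}")
    ant, post, origins = [], [], []
    for r0 in range(0, H - PATCH_SIZE + 1, PATCH_STRIDE):
        for c0 in range(0, W - PATCH_SIZE + 1, PATCH_STRIDE):
            foot = np.asarray(mask)[r0:r0 + PATCH_SIZE, c0:c0 + PATCH_SIZE]
            if foot.any():
                ant.append(pair.anterior[r0:r0 + PATCH_SIZE, c0:c0 + PATCH_SIZE])
                post.append(pair.posterior[r0:r0 + PATCH_SIZE, c0:c0 + PATCH_SIZE])
                origins.append((r0, c0))
    if origins:
        return PatchSet(anterior=np.stack(ant), posterior=np.stack(post),
                        origins=np.asarray(origins), image_shape=(H, W))
    return PatchSet(anterior=np.zeros((0, PATCH_SIZE, PATCH_SIZE)),
                    posterior=np.zeros((0, PATCH_SIZE, PATCH_SIZE)),
                    origins=np.zeros((0, 2), dtype=int), image_shape=(H, W))


#: logits assigned to pixels no patch covers: the "others" class wins
UNCOVERED_LOGIT = 20.0


def assemble_patches(patch_logits: list[np.ndarray] | np.ndarray,
                     origins: np.ndarray, output_shape: tuple[int, int]
                     ) -> np.ndarray:
    """Average per-patch ``(C, 64, 64)`` logit rasters back into a full
    ``(C, H, W)`` field; overlapping patches are averaged, uncovered pixels
    get an "others"-wins logit vector."""
    patch_logits = [np.asarray(p, dtype=np.float64) for p in patch_logits]
    if len(patch_logits) != len(origins):
        raise ValueError("one origin per patch required")
    if np.any(np.asarray(origins) % PATCH_STRIDE):
        raise ValueError("origins must lie on the stride grid")
    if patch_logits:
        shapes = {p.shape for p in patch_logits}
        if len(shapes) != 1:
            raise ValueError(f"mismatched patch logit shapes: {shapes}")
        C = patch_logits[0].shape[0]
    else:
        C = 3
    acc = np.zeros((C,) + tuple(output_shape))
    cnt = np.zeros(output_shape)
    for p, (r0, c0) in zip(patch_logits, np.asarray(origins, dtype=int)):
        k = p.shape[1]
        acc[:, r0:r0 + k, c0:c0 + k] += p
        cnt[r0:r0 + k, c0:c0 + k] += 1
    covered = cnt > 0
    out = np.full((C,) + tuple(output_shape), -UNCOVERED_LOGIT)
    out[OTHERS] = UNCOVERED_LOGIT
    out[:, covered] = acc[:, covered] / cnt[covered]
    return out


def invert_standardization(labels: np.ndarray, t: StandardizationTransform,
                           output_shape: tuple[int, int]) -> np.ndarray:
    """Resample a label raster back into the original input frame with
    nearest-neighbour interpolation."""
    if not t.is_invertible:
        raise PreprocessError("transform is not invertible")
    inv = t.inverse()
    out = inv.warp_image(np.asarray(labels, dtype=np.float64), output_shape,
                         order=0, cval=0.0)
    return np.rint(out).astype(np.asarray(labels).dtype)


def central_crop(raster: np.ndarray, crop_width: int) -> tuple[np.ndarray, int]:
    """Crop ``crop_width`` columns centered on the raster (the standardized
    body axis sits at the center column). Returns the crop and its first
    column for later uncropping."""
    H, W = raster.shape[-2:]
    if crop_width > W:
        raise PreprocessError(f"crop width {crop_width} exceeds raster width {W}")
    c0 = (W - crop_width) // 2
    return raster[..., c0:c0 + crop_width], c0


def uncrop_labels(labels: np.ndarray, c0: int, full_shape: tuple[int, int],
                  fill: int = 0) -> np.ndarray:
    out = np.full(full_shape, fill, dtype=labels.dtype)
    out[:, c0:c0 + labels.shape[1]] = labels
    return out
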