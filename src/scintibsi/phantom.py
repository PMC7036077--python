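"""Seeded generator of paired anterior/posterior scintigram phantoms.

The phantom stands in for clinical whole-body bone scans: a stylized 2-D
skeleton atlas (12 named bones drawn as ellipses, capsules and elliptical
rings in body coordinates) is projected into an anterior view and a
horizontally mirrored posterior view, per-bone tracer uptake plus
physiological kidney/bladder uptake is accumulated, focal hot spots
(metastatic inside bones, benign preferentially at joints) are added, and
Poisson count noise is applied. Anatomical realism is not the goal;
label-structure realism is: the posterior view lacks sternum and clavicle
and carries a dedicated rib∩scapula overlap class, and the posterior view
is produced pre-flipped (as acquired) so the alignment path is exercised.

Body coordinates: ``y`` runs 0 (head top) to 1 (toe tip) in units of body
height; ``x`` is in the same units, centered on the body axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labels import (ANTERIOR_INDEX, BONES_ANTERIOR_ONLY, METASTATIC,
                     NON_MALIGNANT, POSTERIOR_INDEX, RIB_SCAPULA_OVERLAP,
                     SkeletonLabelMap)
from .preprocess import ScintigramPair

__all__ = ["PhantomSpec", "PhantomCase", "ThreefoldSplit", "PhantomError",
           "generate_phantom", "generate_dataset", "threefold_split",
           "DEFAULT_BONE_GEOMETRY", "DEFAULT_BASE_UPTAKE",
           "DEFAULT_PHYSIOLOGICAL_SITES"]


class PhantomError(ValueError):
    """Invalid phantom geometry (e.g. a lesion outside every bone)."""


# --- stylized atlas ---------------------------------------------------------

def _ellipse(cx, cy, sx, sy):
    return {"type": "ellipse", "center": (cx, cy), "semi": (sx, sy)}


def _capsule(x1, y1, x2, y2, r):
    return {"type": "capsule", "p1": (x1, y1), "p2": (x2, y2), "r": r}


def _ring(cx, cy, ox, oy, ix, iy):
    return {"type": "ring", "center": (cx, cy), "semi_outer": (ox, oy),
            "semi_inner": (ix, iy)}


#: body silhouette (soft tissue) parts
BODY_SILHOUETTE = [
    _ellipse(0.0, 0.065, 0.062, 0.060),            # head
    _capsule(0.0, 0.10, 0.0, 0.16, 0.032),         # neck
    _ellipse(0.0, 0.28, 0.130, 0.170),             # torso
    _ellipse(0.0, 0.44, 0.115, 0.070),             # hips
    _capsule(-0.115, 0.18, -0.150, 0.42, 0.032),   # arms
    _capsule(0.115, 0.18, 0.150, 0.42, 0.032),
    _capsule(-0.060, 0.46, -0.075, 0.95, 0.050),   # legs
    _capsule(0.060, 0.46, 0.075, 0.95, 0.050),
]

#: per-bone parametric shapes; left/right limbs are one label each
DEFAULT_BONE_GEOMETRY = {
    "skull": [_ellipse(0.0, 0.065, 0.048, 0.048)],
    "cervical_vertebrae": [_capsule(0.0, 0.115, 0.0, 0.165, 0.013)],
    "thoracic_vertebrae": [_capsule(0.0, 0.165, 0.0, 0.31, 0.016)],
    "lumbar_vertebrae": [_capsule(0.0, 0.31, 0.0, 0.385, 0.019)],
    "sacrum": [_ellipse(0.0, 0.415, 0.028, 0.030)],
    "pelvis": [_ring(0.0, 0.44, 0.105, 0.062, 0.052, 0.035)],
    "rib": [_ring(0.0, 0.235, 0.115, 0.095, 0.058, 0.075)],
    "scapula": [_ellipse(-0.085, 0.205, 0.028, 0.045),
                _ellipse(0.085, 0.205, 0.028, 0.045)],
    "humerus": [_capsule(-0.118, 0.185, -0.138, 0.32, 0.015),
                _capsule(0.118, 0.185, 0.138, 0.32, 0.015)],
    "femur": [_capsule(-0.062, 0.47, -0.072, 0.70, 0.020),
              _capsule(0.062, 0.47, 0.072, 0.70, 0.020)],
    "sternum": [_capsule(0.0, 0.195, 0.0, 0.275, 0.016)],
    "clavicle": [_capsule(-0.020, 0.162, -0.098, 0.150, 0.009),
                 _capsule(0.020, 0.162, 0.098, 0.150, 0.009)],
}

#: paint order for label maps; later entries overwrite earlier ones
ANTERIOR_PAINT_ORDER = ["rib", "scapula", "humerus", "skull", "pelvis",
                        "femur", "sacrum", "cervical_vertebrae",
                        "thoracic_vertebrae", "lumbar_vertebrae",
                        "sternum", "clavicle"]
POSTERIOR_PAINT_ORDER = ["rib", "scapula", "humerus", "skull", "pelvis",
                         "femur", "sacrum", "cervical_vertebrae",
                         "thoracic_vertebrae", "lumbar_vertebrae"]

#: mean added count rate over soft tissue, per bone
DEFAULT_BASE_UPTAKE = {
    "skull": 26.0, "cervical_vertebrae": 22.0, "thoracic_vertebrae": 24.0,
    "lumbar_vertebrae": 26.0, "sacrum": 24.0, "pelvis": 26.0, "rib": 18.0,
    "scapula": 18.0, "humerus": 16.0, "femur": 18.0, "sternum": 20.0,
    "clavicle": 16.0,
}

SOFT_TISSUE_UPTAKE = 7.0
AIR_UPTAKE = 0.3

#: physiological (non-osseous) uptake sites: shape, mean intensity and the
#: anterior/posterior visibility factors (kidneys sit dorsally)
DEFAULT_PHYSIOLOGICAL_SITES = [
    {"name": "kidney_left", "shape": _ellipse(-0.055, 0.335, 0.025, 0.035),
     "intensity": 45.0, "view_factor": (0.7, 1.3)},
    {"name": "kidney_right", "shape": _ellipse(0.055, 0.335, 0.025, 0.035),
     "intensity": 45.0, "view_factor": (0.7, 1.3)},
    {"name": "bladder", "shape": _ellipse(0.0, 0.46, 0.022, 0.025),
     "intensity": 55.0, "view_factor": (1.2, 0.8)},
]

#: joint sites for benign lesions: (x, y) center and the owning bone
JOINT_SITES = [
    ((-0.118, 0.19), "humerus"), ((0.118, 0.19), "humerus"),   # shoulders
    ((-0.135, 0.31), "humerus"), ((0.135, 0.31), "humerus"),   # elbows
    ((-0.063, 0.475), "femur"), ((0.063, 0.475), "femur"),     # hips
    ((-0.071, 0.69), "femur"), ((0.071, 0.69), "femur"),       # knees
    ((0.0, 0.41), "sacrum"),                                   # lumbosacral
]


def _shape_mask(shape: dict, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    kind = shape["type"]
    if kind == "ellipse":
        cx, cy = shape["center"]
        sx, sy = shape["semi"]
        return ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 <= 1.0
    if kind == "capsule":
        x1, y1 = shape["p1"]
        x2, y2 = shape["p2"]
        r = shape["r"]
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 < 1e-12:
            return (X - x1) ** 2 + (Y - y1) ** 2 <= r * r
        t = np.clip(((X - x1) * dx + (Y - y1) * dy) / L2, 0.0, 1.0)
        return (X - (x1 + t * dx)) ** 2 + (Y - (y1 + t * dy)) ** 2 <= r * r
    if kind == "ring":
        cx, cy = shape["center"]
        ox, oy = shape["semi_outer"]
        ix, iy = shape["semi_inner"]
        outer = ((X - cx) / ox) ** 2 + ((Y - cy) / oy) ** 2 <= 1.0
        inner = ((X - cx) / ix) ** 2 + ((Y - cy) / iy) ** 2 < 1.0
        return outer & ~inner
    raise PhantomError(f"unknown shape type {kind!r}")


def _union_mask(shapes: list[dict], X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    mask = np.zeros(X.shape, dtype=bool)
    for s in shapes:
        mask |= _shape_mask(s, X, Y)
    return mask


# --- specification ----------------------------------------------------------

@dataclass
class PhantomSpec:
    """Study conditions for one synthetic case (seeded and reproducible)."""

    image_height_px: int = 320
    image_width_px: int = 160
    bone_geometry: dict = field(default_factory=lambda: dict(DEFAULT_BONE_GEOMETRY))
    base_uptake: dict = field(default_factory=lambda: dict(DEFAULT_BASE_UPTAKE))
    n_met_lesions: int = 3
    n_benign_lesions: int = 2
    lesion_intensity_range: tuple[float, float] = (40.0, 90.0)
    benign_intensity_range: tuple[float, float] = (15.0, 35.0)
    physiological_sites: list = field(
        default_factory=lambda: [dict(s) for s in DEFAULT_PHYSIOLOGICAL_SITES])
    noise_model: str = "poisson"      # "poisson" | "none"
    seed: int = 0
    # separate noise stream: lets many noisy renders share one geometry
    noise_seed: int | None = None
    # pose variability (drawn per case)
    rotation_max_deg: float = 4.0
    body_height_fraction: tuple[float, float] = (0.86, 0.94)
    posterior_shift_max_px: int = 4
    # lesion geometry in body units
    met_radius_range: tuple[float, float] = (0.010, 0.022)
    benign_radius_range: tuple[float, float] = (0.008, 0.016)
    # per-case lesion-count ranges used by generate_dataset
    n_met_lesions_range: tuple[int, int] = (0, 6)
    n_benign_lesions_range: tuple[int, int] = (0, 3)

    def __post_init__(self):
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise PhantomError("image dimensions must be positive")
        if self.n_met_lesions < 0 or self.n_benign_lesions < 0:
            raise PhantomError("lesion counts must be non-negative")
        if self.lesion_intensity_range[0] <= 0:
            raise PhantomError("lesion intensities must be positive")
        if self.noise_model not in ("poisson", "none"):
            raise PhantomError(f"unknown noise model {self.noise_model!r}")


@dataclass
class PhantomCase:
    """One synthetic case: noisy pair, ground-truth rasters, true BSI."""

    pair: ScintigramPair
    skeleton_truth: SkeletonLabelMap
    hotspot_truth_anterior: np.ndarray
    hotspot_truth_posterior: np.ndarray
    true_bsi: float
    expected_anterior: np.ndarray | None = None
    expected_posterior: np.ndarray | None = None
    lesions: list = field(default_factory=list)


# --- rendering --------------------------------------------------------------

def _body_grids(spec: PhantomSpec, rng: np.random.Generator):
    """Per-view pixel->body-coordinate grids and the sampled pose."""
    H, W = spec.image_height_px, spec.image_width_px
    theta = np.deg2rad(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg))
    frac = rng.uniform(*spec.body_height_fraction)
    L = frac * H
    jitter = rng.uniform(-0.02, 0.02, size=2)
    rc, cc = H / 2.0 + jitter[0] * H, W / 2.0 + jitter[1] * W
    dr = int(rng.integers(-spec.posterior_shift_max_px, spec.posterior_shift_max_px + 1))
    dc = int(rng.integers(-spec.posterior_shift_max_px, spec.posterior_shift_max_px + 1))

    def grids(row_off: float, col_off: float, mirror: bool):
        rows = np.arange(H, dtype=np.float64)[:, None] - rc - row_off
        cols = np.arange(W, dtype=np.float64)[None, :] - cc - col_off
        c, s = np.cos(theta), np.sin(theta)
        # body frame: y along the (rotated) body axis, x across it
        Yc = (c * rows + s * cols) / L
        X = (-s * rows + c * cols) / L
        Y = Yc + 0.5
        if mirror:
            X = -X
        return X, Y

    ant = grids(0.0, 0.0, mirror=False)
    post = grids(float(dr), float(dc), mirror=True)
    pose = {"rotation_deg": float(np.rad2deg(theta)), "height_fraction": float(frac),
            "posterior_shift_px": (dr, dc)}
    return ant, post, pose


def _paint_labels(bone_masks: dict, order: list[str], index: dict,
                  shape: tuple[int, int], overlap: bool) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.uint8)
    for name in order:
        if name in bone_masks:
            labels[bone_masks[name]] = index[name]
    if overlap and "rib" in bone_masks and "scapula" in bone_masks:
        labels[bone_masks["rib"] & bone_masks["scapula"]] = index[RIB_SCAPULA_OVERLAP]
    return labels


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator,
                   bones_ant: dict, bones_post: dict,
                   grids_ant, grids_post):
    """Sample lesion centers/radii and rasterize per-view lesion masks."""
    Xa, Ya = grids_ant
    Xp, Yp = grids_post
    lesions = []  # (kind, bone, center, radius, intensity, mask_ant, mask_post)

    def add(kind: str, bone: str, center: tuple[float, float], radius: float,
            intensity: float):
        cx, cy = center
        ma = ((Xa - cx) ** 2 + (Ya - cy) ** 2 <= radius ** 2) & bones_ant[bone]
        if bone in BONES_ANTERIOR_ONLY:
            mp = np.zeros_like(ma)
        else:
            mp = ((Xp - cx) ** 2 + (Yp - cy) ** 2 <= radius ** 2) & bones_post[bone]
        if not ma.any() and not mp.any():
            raise PhantomError(
                f"lesion at {center} has no pixels inside bone {bone!r}")
        lesions.append({"kind": kind, "bone": bone, "center": center,
                        "radius": radius, "intensity": intensity,
                        "mask_ant": ma, "mask_post": mp})

    bone_names = [b for b in spec.bone_geometry if bones_ant[b].any()]
    if spec.n_met_lesions > 0 and not bone_names:
        raise PhantomError("no bone has pixels; cannot place lesions")
    for _ in range(spec.n_met_lesions):
        bone = bone_names[rng.integers(len(bone_names))]
        ys, xs = np.nonzero(bones_ant[bone])
        k = rng.integers(len(ys))
        center = (float(Xa[ys[k], xs[k]]), float(Ya[ys[k], xs[k]]))
        add("metastatic", bone, center, rng.uniform(*spec.met_radius_range),
            rng.uniform(*spec.lesion_intensity_range))
    for _ in range(spec.n_benign_lesions):
        if rng.uniform() < 0.8:  # preferentially at joints
            (jx, jy), bone = JOINT_SITES[rng.integers(len(JOINT_SITES))]
            center = (jx + rng.uniform(-0.005, 0.005),
                      jy + rng.uniform(-0.005, 0.005))
        else:
            bone = bone_names[rng.integers(len(bone_names))]
            ys, xs = np.nonzero(bones_ant[bone])
            k = rng.integers(len(ys))
            center = (float(Xa[ys[k], xs[k]]), float(Ya[ys[k], xs[k]]))
        try:
            add("benign", bone, center, rng.uniform(*spec.benign_radius_range),
                rng.uniform(*spec.benign_intensity_range))
        except PhantomError:
            # jittered joint center fell outside the bone; retry at the bone
            ys, xs = np.nonzero(bones_ant[bone])
            k = rng.integers(len(ys))
            center = (float(Xa[ys[k], xs[k]]), float(Ya[ys[k], xs[k]]))
            add("benign", bone, center, rng.uniform(*spec.benign_radius_range),
                rng.uniform(*spec.benign_intensity_range))
    return lesions


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one seeded phantom case.

    The anterior and posterior views share the skeleton geometry; the
    posterior is rendered as the horizontally mirrored projection (with a
    small acquisition shift) and carries the posterior label table.
    Deterministic given ``spec.seed``.
    """
    from .bsi import compute_bsi, default_weight_table  # deferred: no cycle at import

    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height_px, spec.image_width_px
    grids_ant, grids_post, pose = _body_grids(spec, rng)

    silhouette = {}
    bones = {}
    for view, (X, Y) in (("ant", grids_ant), ("post", grids_post)):
        silhouette[view] = _union_mask(BODY_SILHOUETTE, X, Y)
        bones[view] = {name: _union_mask(shapes, X, Y) & silhouette[view]
                       for name, shapes in spec.bone_geometry.items()}

    skeleton = SkeletonLabelMap(
        anterior=_paint_labels(bones["ant"], ANTERIOR_PAINT_ORDER,
                               ANTERIOR_INDEX, (H, W), overlap=False),
        posterior=_paint_labels(bones["post"], POSTERIOR_PAINT_ORDER,
                                POSTERIOR_INDEX, (H, W), overlap=True))

    lesions = _place_lesions(spec, rng, bones["ant"], bones["post"],
                             grids_ant, grids_post)

    expected = {}
    hotspots = {}
    for view, (X, Y) in (("ant", grids_ant), ("post", grids_post)):
        img = np.full((H, W), AIR_UPTAKE)
        img[silhouette[view]] += SOFT_TISSUE_UPTAKE
        for name, mask in bones[view].items():
            img[mask] += spec.base_uptake.get(name, 0.0)
        vf = 0 if view == "ant" else 1
        for site in spec.physiological_sites:
            m = _shape_mask(site["shape"], X, Y) & silhouette[view]
            img[m] += site["intensity"] * site.get("view_factor", (1.0, 1.0))[vf]
        hot = np.zeros((H, W), dtype=np.uint8)
        for les in lesions:
            m = les["mask_ant"] if view == "ant" else les["mask_post"]
            img[m] += les["intensity"]
            hot[m] = METASTATIC if les["kind"] == "metastatic" else NON_MALIGNANT
        expected[view] = img
        hotspots[view] = hot

    noise_rng = (rng if spec.noise_seed is None
                 else np.random.default_rng(spec.noise_seed))
    if spec.noise_model == "poisson":
        ant = noise_rng.poisson(expected["ant"]).astype(np.uint16)
        post = noise_rng.poisson(expected["post"]).astype(np.uint16)
    else:
        ant = np.rint(expected["ant"]).astype(np.uint16)
        post = np.rint(expected["post"]).astype(np.uint16)

    pair = ScintigramPair(anterior=ant, posterior=post,
                          meta={"pose": pose, "synthetic": True})
    report = compute_bsi(skeleton, {"anterior": hotspots["ant"],
                                    "posterior": hotspots["post"]},
                         default_weight_table())
    return PhantomCase(pair=pair, skeleton_truth=skeleton,
                       hotspot_truth_anterior=hotspots["ant"],
                       hotspot_truth_posterior=hotspots["post"],
                       true_bsi=report.total_bsi,
                       expected_anterior=expected["ant"],
                       expected_posterior=expected["post"],
                       lesions=[{k: v for k, v in les.items()
                                 if not k.startswith("mask")} for les in lesions])


# --- dataset + threefold split ---------------------------------------------

@dataclass
class ThreefoldSplit:
    """Six folds: three held-out groups, each used twice with validation
    and test halves swapped (so every case is tested once per orientation)."""

    folds: list[dict]

    def __len__(self):
        return len(self.folds)


def threefold_split(case_ids: list, seed: int = 0) -> ThreefoldSplit:
    """Partition ``case_ids`` into three equal (±1) groups; per fold, two
    groups train and the held-out group is halved into validation and test."""
    ids = list(case_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 cases for a threefold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    groups = [sorted(order[g::3].tolist()) for g in range(3)]
    groups = [[ids[i] for i in g] for g in groups]
    folds = []
    for g in range(3):
        train = [i for k in range(3) if k != g for i in groups[k]]
        held = groups[g]
        half = len(held) // 2
        folds.append({"train": train, "val": held[:half], "test": held[half:]})
        folds.append({"train": train, "val": held[half:], "test": held[:half]})
    return ThreefoldSplit(folds=folds)


def generate_dataset(n_cases: int, spec: PhantomSpec, seed: int
                     ) -> tuple[list[PhantomCase], ThreefoldSplit]:
    """Generate ``n_cases`` phantoms (per-case lesion counts drawn from the
    spec's ranges) plus the threefold cross-validation split descriptor."""
    if n_cases < 3:
        raise ValueError("need at least 3 cases")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        n_met = int(rng.integers(spec.n_met_lesions_range[0],
                                 spec.n_met_lesions_range[1] + 1))
        n_ben = int(rng.integers(spec.n_benign_lesions_range[0],
                                 spec.n_benign_lesions_range[1] + 1))
        cases.append(generate_phantom(replace(
            spec, seed=case_seed, n_met_lesions=n_met, n_benign_lesions=n_ben)))
    return cases, threefold_split(list(range(n_cases)), seed=seed)
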