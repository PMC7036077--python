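"""End-to-end orchestration: phantom generation -> preprocessing -> training
-> inference -> BSI -> evaluation.

The stages follow the measurement pipeline's order: posterior flip and
alignment, spatial standardization, grey normalization; skeleton
segmentation on the central crop of the standardized pair; hot-spot
extraction on 64x64 patch pairs with logit averaging at overlaps; the
three-way threshold rule calibrated to a per-lesion sensitivity target;
inverse transforms back to the acquired frames; BSI scoring against the
segmented bones.

Configuration is a plain nested dict (YAML-friendly); see
``configs/desk.yaml`` for the desk-scale profile and ``configs/paper.yaml``
for the full-scale settings.
"""

from __future__ import annotations

import copy
import hashlib
import json

import numpy as np
from scipy import ndimage

from .bsi import BoneWeightTable, compute_bsi, default_weight_table
from .evaluation import (bsi_correlation, false_positive_stats,
                         lesion_sensitivity, per_bone_dice)
from .inference import (HotspotField, Threshold, calibrate_threshold,
                        classify_hotspots, segment_skeleton)
from .labels import SkeletonLabelMap
from .networks import (BtrflyConfig, BtrflyNet, build_btrflynet,
                       build_btrflynet_dsv, build_resbtrflynet,
                       forward as net_forward)
from .phantom import PhantomCase, PhantomSpec, generate_dataset
from .preprocess import (ScintigramPair, assemble_patches, body_mask,
                         central_crop, flip_and_align, invert_standardization,
                         normalize_grey, spatially_standardize, tile_patches,
                         uncrop_labels)
from .training import OptimizerSchedule, he_initialize, train_hotspot, train_skeleton

__all__ = ["DEFAULT_CONFIG", "prepare_case", "build_skeleton_training_set",
           "build_patch_training_set", "train_pipeline_networks",
           "predict_skeleton", "predict_hotspots", "run_case", "run_end_to_end"]


DEFAULT_CONFIG: dict = {
    "profile": "desk",
    "phantom": {"n_cases": 12, "image_height_px": 320, "image_width_px": 160,
                "seed": 0},
    "preprocess": {"output_spacing_mm": 8.0, "crop_width": 128},
    "networks": {
        "skeleton": {"depth": 3, "base_channels": 4, "input_shape": [96, 48],
                     "use_dsv": True},
        "hotspot": {"depth": 2, "base_channels": 6, "input_shape": [64, 64],
                    "use_residual": True},
    },
    "training": {
        "skeleton": {"batch_size": 4, "max_iterations": 1100,
                     "alpha_decay_iteration": 900, "eval_every": 100, "seed": 1},
        "hotspot": {"batch_size": 8, "max_iterations": 900, "eval_every": 100,
                    "seed": 2},
    },
    "inference": {"target_sensitivity": 0.9},
}


def merged_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            for k2, v2 in val.items():
                if isinstance(v2, dict) and isinstance(cfg[key].get(k2), dict):
                    cfg[key][k2].update(v2)
                else:
                    cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


# --- per-case preprocessing -------------------------------------------------

def prepare_case(pair: ScintigramPair, cfg: dict,
                 skeleton_truth: SkeletonLabelMap | None = None,
                 hotspot_truth: dict | None = None) -> dict:
    """Run the shared geometric/intensity normalization for one pair.

    Returns the standardized normalized pair, the transforms needed to map
    results back to the acquired frames and (when ground truth is supplied)
    the truth rasters warped into the standardized frame for training.
    """
    spacing = cfg["preprocess"]["output_spacing_mm"]
    aligned, t_align = flip_and_align(pair)
    std, t_std = spatially_standardize(aligned, output_spacing_mm=spacing)
    mask = (body_mask(std.anterior) | body_mask(std.posterior)).astype(np.uint8)
    norm_ant = normalize_grey(std.anterior, mask)
    norm_post = normalize_grey(std.posterior, mask)
    out = {"pair": pair, "std_pair": std, "t_align": t_align, "t_std": t_std,
           "t_post_total": t_std.compose(t_align), "mask": mask,
           "norm_anterior": norm_ant, "norm_posterior": norm_post,
           "orig_shape": pair.anterior.shape}
    if skeleton_truth is not None:
        out["skel_truth_std"] = SkeletonLabelMap(
            anterior=_warp_labels(skeleton_truth.anterior, t_std, std.shape),
            posterior=_warp_labels(skeleton_truth.posterior,
                                   out["t_post_total"], std.shape))
    if hotspot_truth is not None:
        out["hot_truth_std"] = {
            "anterior": _warp_labels(hotspot_truth["anterior"], t_std, std.shape),
            "posterior": _warp_labels(hotspot_truth["posterior"],
                                      out["t_post_total"], std.shape)}
    return out


def _warp_labels(labels, transform, shape):
    return np.rint(transform.warp_image(np.asarray(labels, dtype=np.float64),
                                        shape, order=0)).astype(np.uint8)


def prepare_phantom_case(case: PhantomCase, cfg: dict) -> dict:
    return prepare_case(case.pair, cfg, skeleton_truth=case.skeleton_truth,
                        hotspot_truth={"anterior": case.hotspot_truth_anterior,
                                       "posterior": case.hotspot_truth_posterior})


# --- training-set assembly --------------------------------------------------

def _crop_resize(img: np.ndarray, crop_width: int, net_shape: tuple[int, int],
                 order: int) -> np.ndarray:
    crop, _ = central_crop(img, crop_width)
    zoom = (net_shape[0] / crop.shape[0], net_shape[1] / crop.shape[1])
    return ndimage.zoom(crop, zoom, order=order, prefilter=order > 1,
                        grid_mode=True, mode="grid-constant")


def build_skeleton_training_set(prepped: list[dict], cfg: dict) -> list[dict]:
    """Central-crop + resize the standardized pairs and truth labels to the
    skeleton network's input shape."""
    crop_w = cfg["preprocess"]["crop_width"]
    net_shape = tuple(cfg["networks"]["skeleton"]["input_shape"])
    out = []
    for p in prepped:
        out.append({
            "anterior": _crop_resize(p["norm_anterior"], crop_w, net_shape, 1),
            "posterior": _crop_resize(p["norm_posterior"], crop_w, net_shape, 1),
            "anterior_labels": _crop_resize(p["skel_truth_std"].anterior,
                                            crop_w, net_shape, 0).astype(np.uint8),
            "posterior_labels": _crop_resize(p["skel_truth_std"].posterior,
                                             crop_w, net_shape, 0).astype(np.uint8),
        })
    return out


def build_patch_training_set(prepped: list[dict], cfg: dict) -> dict:
    """Tile the standardized normalized pairs into 64x64 patch pairs with
    3-class targets from the warped hot-spot truth."""
    ants, posts, las, lps = [], [], [], []
    for p in prepped:
        norm_pair = ScintigramPair(anterior=np.maximum(p["norm_anterior"], 0),
                                   posterior=np.maximum(p["norm_posterior"], 0),
                                   pixel_spacing_mm=p["std_pair"].pixel_spacing_mm)
        patches = tile_patches(norm_pair, p["mask"])
        for (r0, c0), ant, post in zip(patches.origins, patches.anterior,
                                       patches.posterior):
            ants.append(ant)
            posts.append(post)
            las.append(p["hot_truth_std"]["anterior"][r0:r0 + 64, c0:c0 + 64])
            lps.append(p["hot_truth_std"]["posterior"][r0:r0 + 64, c0:c0 + 64])
    if not ants:
        raise ValueError("no patches intersect the body mask")
    return {"anterior": np.stack(ants), "posterior": np.stack(posts),
            "anterior_labels": np.stack(las).astype(np.int64),
            "posterior_labels": np.stack(lps).astype(np.int64)}


# --- network construction / training ---------------------------------------

def build_networks(cfg: dict) -> tuple[BtrflyNet, BtrflyNet]:
    sk = cfg["networks"]["skeleton"]
    hs = cfg["networks"]["hotspot"]
    skel_cfg = BtrflyConfig(task="skeleton", input_shape=tuple(sk["input_shape"]),
                            depth=sk["depth"], base_channels=sk["base_channels"],
                            use_dsv=sk.get("use_dsv", False))
    hot_cfg = BtrflyConfig(task="hotspot", input_shape=tuple(hs["input_shape"]),
                           depth=hs["depth"], base_channels=hs["base_channels"],
                           use_residual=hs.get("use_residual", True))
    skel_net = (build_btrflynet_dsv(skel_cfg) if skel_cfg.use_dsv
                else build_btrflynet(skel_cfg))
    hot_net = (build_resbtrflynet(hot_cfg) if hot_cfg.use_residual
               else build_btrflynet(hot_cfg))
    return skel_net, hot_net


def _schedule(d: dict) -> OptimizerSchedule:
    return OptimizerSchedule(
        alpha=d.get("alpha", 0.001), beta1=d.get("beta1", 0.9),
        beta2=d.get("beta2", 0.999), eps=d.get("eps", 1e-8),
        alpha_decay_iteration=d.get("alpha_decay_iteration"),
        alpha_decay_factor=d.get("alpha_decay_factor", 0.1),
        batch_size=d["batch_size"], max_iterations=d["max_iterations"],
        eval_every=d["eval_every"], seed=d.get("seed", 0))


def train_pipeline_networks(train_prepped: list[dict], val_prepped: list[dict],
                            cfg: dict):
    """Train both networks on prepared cases; returns the trained networks,
    their histories and the calibrated hot-spot threshold."""
    skel_net, hot_net = build_networks(cfg)
    he_initialize(skel_net, cfg["training"]["skeleton"].get("seed", 1))
    he_initialize(hot_net, cfg["training"]["hotspot"].get("seed", 2))

    skel_train = build_skeleton_training_set(train_prepped, cfg)
    skel_val = build_skeleton_training_set(val_prepped, cfg)
    skel_net, skel_hist = train_skeleton(skel_net, skel_train, skel_val,
                                         _schedule(cfg["training"]["skeleton"]))

    hot_train = build_patch_training_set(train_prepped, cfg)
    hot_val = build_patch_training_set(val_prepped, cfg)
    hot_net, hot_hist = train_hotspot(hot_net, hot_train, hot_val,
                                      _schedule(cfg["training"]["hotspot"]))

    fields, truths = [], []
    for p in val_prepped:
        per_view = predict_hotspot_fields(hot_net, p)
        for view in ("anterior", "posterior"):
            fields.append(per_view[view])
            truths.append(p["hot_truth_std"][view])
    th = calibrate_threshold(fields, truths,
                             cfg["inference"]["target_sensitivity"])
    return skel_net, skel_hist, hot_net, hot_hist, th


# --- inference --------------------------------------------------------------

def predict_skeleton(net: BtrflyNet, prepped: dict, cfg: dict) -> SkeletonLabelMap:
    """Segment the skeleton and return labels in the acquired frames."""
    crop_w = cfg["preprocess"]["crop_width"]
    net_shape = tuple(net.cfg.input_shape)
    std_shape = prepped["std_pair"].shape
    ant_in = _crop_resize(prepped["norm_anterior"], crop_w, net_shape, 1)
    post_in = _crop_resize(prepped["norm_posterior"], crop_w, net_shape, 1)
    logits = net_forward(net, ant_in, post_in)
    labels_net = segment_skeleton(logits)
    out = {}
    for view, lab in (("anterior", labels_net.anterior),
                      ("posterior", labels_net.posterior)):
        up = ndimage.zoom(lab, (std_shape[0] / net_shape[0], crop_w / net_shape[1]),
                          order=0)
        full = uncrop_labels(up.astype(np.uint8), (std_shape[1] - crop_w) // 2,
                             std_shape)
        out[view] = full
    ant_acq = invert_standardization(out["anterior"], prepped["t_std"],
                                     prepped["orig_shape"])
    post_acq = invert_standardization(out["posterior"], prepped["t_post_total"],
                                      prepped["orig_shape"])
    return SkeletonLabelMap(anterior=ant_acq, posterior=post_acq)


def predict_hotspot_fields(net: BtrflyNet, prepped: dict,
                           chunk: int = 64) -> dict[str, HotspotField]:
    """Per-view hot-spot probability fields in the standardized frame,
    assembled by averaging patch logits at overlaps."""
    from . import nn

    norm_pair = ScintigramPair(anterior=np.maximum(prepped["norm_anterior"], 0),
                               posterior=np.maximum(prepped["norm_posterior"], 0))
    patches = tile_patches(norm_pair, prepped["mask"])
    if len(patches) == 0:
        raise ValueError("no patches intersect the body mask")
    net.eval()
    logits_a, logits_p = [], []
    for s in range(0, len(patches), chunk):
        sl = slice(s, min(s + chunk, len(patches)))
        a = nn.Tensor(patches.anterior[sl][:, None].astype(np.float64))
        p = nn.Tensor(patches.posterior[sl][:, None].astype(np.float64))
        ya, yp, _ = net.forward(a, p)
        logits_a.extend(ya.data)
        logits_p.extend(yp.data)
    shape = prepped["std_pair"].shape
    return {"anterior": HotspotField.from_logits(
                assemble_patches(logits_a, patches.origins, shape)),
            "posterior": HotspotField.from_logits(
                assemble_patches(logits_p, patches.origins, shape))}


def predict_hotspots(net: BtrflyNet, prepped: dict, th: Threshold
                     ) -> tuple[dict, dict]:
    """Hot-spot label rasters in the standardized and acquired frames."""
    fields = predict_hotspot_fields(net, prepped)
    std_labels = {v: classify_hotspots(fields[v], th)
                  for v in ("anterior", "posterior")}
    acq_labels = {
        "anterior": invert_standardization(std_labels["anterior"],
                                           prepped["t_std"], prepped["orig_shape"]),
        "posterior": invert_standardization(std_labels["posterior"],
                                            prepped["t_post_total"],
                                            prepped["orig_shape"])}
    return std_labels, acq_labels


# --- end-to-end -------------------------------------------------------------

def run_case(skel_net: BtrflyNet, hot_net: BtrflyNet, th: Threshold,
             case: PhantomCase, cfg: dict,
             table: BoneWeightTable | None = None) -> dict:
    """Measure one case end-to-end and evaluate against its ground truth."""
    table = table or default_weight_table()
    prepped = prepare_phantom_case(case, cfg)
    skeleton = predict_skeleton(skel_net, prepped, cfg)
    _, hot_acq = predict_hotspots(hot_net, prepped, th)
    report = compute_bsi(skeleton, hot_acq, table)
    dice = per_bone_dice(skeleton, case.skeleton_truth)
    fp = {}
    sens = {}
    for view, truth in (("anterior", case.hotspot_truth_anterior),
                        ("posterior", case.hotspot_truth_posterior)):
        fp[view] = false_positive_stats(hot_acq[view], truth)
        try:
            sens[view] = lesion_sensitivity(hot_acq[view], truth)[0]
        except ValueError:
            sens[view] = None
    return {"report": report, "measured_bsi": report.total_bsi,
            "true_bsi": case.true_bsi, "per_bone_dice": dice,
            "fp_stats": fp, "lesion_sensitivity": sens}


def run_oracle_case(case: PhantomCase, table: BoneWeightTable | None = None
                    ) -> dict:
    """Identity pipeline: ground-truth rasters passed straight to scoring."""
    table = table or default_weight_table()
    report = compute_bsi(case.skeleton_truth,
                         {"anterior": case.hotspot_truth_anterior,
                          "posterior": case.hotspot_truth_posterior}, table)
    return {"report": report, "measured_bsi": report.total_bsi,
            "true_bsi": case.true_bsi}


def run_end_to_end(config: dict | None = None, oracle: bool = False) -> dict:
    """Full pipeline on a synthetic dataset per the config profile.

    Generates the phantom dataset, takes the first cross-validation fold,
    trains both networks (unless ``oracle``), calibrates the threshold on
    the validation fold and measures every test case. Returns reports,
    per-case metrics and a reproducibility manifest.
    """
    cfg = merged_config(config)
    ph = cfg["phantom"]
    spec = PhantomSpec(image_height_px=ph["image_height_px"],
                       image_width_px=ph["image_width_px"], seed=ph["seed"])
    cases, split = generate_dataset(ph["n_cases"], spec, seed=ph["seed"])
    fold = split.folds[0]
    results = {"cases": [], "fold": fold}

    if oracle:
        for i in fold["test"]:
            out = run_oracle_case(cases[i])
            results["cases"].append({"case": i, "measured_bsi": out["measured_bsi"],
                                     "true_bsi": out["true_bsi"]})
    else:
        train_prepped = [prepare_phantom_case(cases[i], cfg) for i in fold["train"]]
        val_prepped = [prepare_phantom_case(cases[i], cfg) for i in fold["val"]]
        skel_net, skel_hist, hot_net, hot_hist, th = train_pipeline_networks(
            train_prepped, val_prepped, cfg)
        results["threshold"] = th.th
        results["histories"] = {"skeleton": skel_hist, "hotspot": hot_hist}
        for i in fold["test"]:
            out = run_case(skel_net, hot_net, th, cases[i], cfg)
            results["cases"].append({"case": i, "measured_bsi": out["measured_bsi"],
                                     "true_bsi": out["true_bsi"],
                                     "detail": out})

    measured = [c["measured_bsi"] for c in results["cases"]]
    true = [c["true_bsi"] for c in results["cases"]]
    try:
        results["bsi_correlation"] = bsi_correlation(measured, true)
    except ValueError:
        results["bsi_correlation"] = None
    results["manifest"] = {
        "config": cfg, "oracle": oracle,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "n_cases": len(cases)}
    return results
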