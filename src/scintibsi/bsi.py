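"""Bone Scan Index measurement.

The BSI expresses the fraction of total skeletal mass involved by
metastatic hot spots: for every bone, the area ratio between its
extracted metastatic hot spots and the bone itself is multiplied by the
bone's skeletal mass fraction (an ICRP-derived weight), and the weighted
ratios are summed. The result is reported in percent.

Matching rule: each 8-connected metastatic component is assigned to the
bone class holding the plurality of its pixels; components that overlap
no bone at all are excluded and listed in the report. The posterior
rib∩scapula overlap class is split equally between rib and scapula (both
its bone area and any hot-spot area), which keeps totals conserved.
Bones visible in both views contribute the mean of their two per-view
contributions; anterior-only bones (sternum, clavicle) contribute their
anterior value.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .labels import (ANTERIOR_CLASSES, BONES_ANTERIOR_ONLY, METASTATIC,
                     POSTERIOR_CLASSES, RIB_SCAPULA_OVERLAP, SkeletonLabelMap)

__all__ = ["BoneWeightTable", "BSIReport", "default_weight_table",
           "match_hotspots_to_bones", "bone_ratio", "compute_bsi"]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class BoneWeightTable:
    """Bone name -> dimensionless skeletal mass fraction."""

    entries: dict[str, float]
    provenance: str = "unspecified"

    def __post_init__(self):
        for bone, frac in self.entries.items():
            if not (0.0 < frac < 1.0):
                raise ValueError(f"weight fraction for {bone!r} must be in (0,1), "
                                 f"got {frac}")

    def __getitem__(self, bone: str) -> float:
        if bone not in self.entries:
            raise KeyError(f"no weight-fraction entry for bone {bone!r}")
        return self.entries[bone]

    def __contains__(self, bone: str) -> bool:
        return bone in self.entries

    @classmethod
    def from_yaml(cls, path) -> "BoneWeightTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(entries={k: float(v) for k, v in doc["weights"].items()},
                   provenance=str(doc.get("provenance", path)))


def default_weight_table() -> BoneWeightTable:
    """The packaged approximate ICRP-derived table."""
    ref = importlib.resources.files("scintibsi.data") / "bone_weights.yaml"
    with importlib.resources.as_file(ref) as path:
        return BoneWeightTable.from_yaml(path)


@dataclass
class BSIReport:
    """Per-bone hot-spot/bone area ratios, weighted contributions and the
    total BSI in percent, with per-view intermediates."""

    per_bone: dict[str, dict]
    total_bsi: float
    view_breakdown: dict[str, dict]
    weight_table_provenance: str = ""
    unassigned_components: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"total_bsi": self.total_bsi, "per_bone": self.per_bone,
                "view_breakdown": self.view_breakdown,
                "weight_table_provenance": self.weight_table_provenance,
                "unassigned_components": self.unassigned_components}


def match_hotspots_to_bones(hotspot_labels: np.ndarray, skeleton_labels: np.ndarray,
                            class_names: tuple[str, ...]
                            ) -> tuple[list[dict], list[dict]]:
    """Assign each 8-connected metastatic component to a bone by plurality
    of its pixel overlap with the skeleton label raster.

    Returns ``(assigned, excluded)``; excluded components overlap only
    background. Ties break toward the lower class index.
    """
    if hotspot_labels.shape != skeleton_labels.shape:
        raise ValueError("hot-spot and skeleton rasters must be co-registered")
    comp, n = ndimage.label(np.asarray(hotspot_labels) == METASTATIC,
                            structure=_EIGHT)
    assigned, excluded = [], []
    for i in range(1, n + 1):
        mask = comp == i
        area = int(mask.sum())
        overlap = np.bincount(np.asarray(skeleton_labels)[mask].ravel(),
                              minlength=len(class_names))
        overlap[0] = 0  # background never receives a lesion
        if overlap.sum() == 0:
            excluded.append({"component": i, "area_px": area})
            continue
        bone = class_names[int(np.argmax(overlap))]
        assigned.append({"component": i, "bone": bone, "area_px": area,
                         "overlap_px": int(overlap.max())})
    return assigned, excluded


def bone_ratio(hotspot_area_px: float, bone_area_px: float) -> float:
    """Hot-spot / bone area ratio, clipped to [0, 1]."""
    if bone_area_px <= 0:
        if hotspot_area_px > 0:
            raise ValueError("hot-spot area on a bone with zero area")
        return 0.0
    return float(min(hotspot_area_px / bone_area_px, 1.0))


def _view_areas(hotspot_labels: np.ndarray, skeleton_labels: np.ndarray,
                class_names: tuple[str, ...]):
    """Per-bone bone/hot-spot pixel areas for one view; the rib∩scapula
    overlap class is split half/half between rib and scapula."""
    bone_area: dict[str, float] = {}
    counts = np.bincount(np.asarray(skeleton_labels).ravel(),
                         minlength=len(class_names))
    for idx, name in enumerate(class_names):
        if idx == 0:
            continue
        if name == RIB_SCAPULA_OVERLAP:
            bone_area["rib"] = bone_area.get("rib", 0.0) + counts[idx] / 2.0
            bone_area["scapula"] = bone_area.get("scapula", 0.0) + counts[idx] / 2.0
        else:
            bone_area[name] = bone_area.get(name, 0.0) + float(counts[idx])
    hot_area: dict[str, float] = {}
    assigned, excluded = match_hotspots_to_bones(hotspot_labels, skeleton_labels,
                                                 class_names)
    for rec in assigned:
        if rec["bone"] == RIB_SCAPULA_OVERLAP:
            hot_area["rib"] = hot_area.get("rib", 0.0) + rec["area_px"] / 2.0
            hot_area["scapula"] = hot_area.get("scapula", 0.0) + rec["area_px"] / 2.0
        else:
            hot_area[rec["bone"]] = hot_area.get(rec["bone"], 0.0) + rec["area_px"]
    return bone_area, hot_area, excluded


def compute_bsi(skeleton: SkeletonLabelMap, hotspot_labels: dict[str, np.ndarray],
                table: BoneWeightTable) -> BSIReport:
    """Measure the BSI from per-view skeleton and hot-spot label rasters.

    ``hotspot_labels`` maps ``"anterior"``/``"posterior"`` to 3-class label
    rasters co-registered with the corresponding skeleton raster.
    """
    views = {
        "anterior": _view_areas(hotspot_labels["anterior"], skeleton.anterior,
                                ANTERIOR_CLASSES),
        "posterior": _view_areas(hotspot_labels["posterior"], skeleton.posterior,
                                 POSTERIOR_CLASSES),
    }
    breakdown: dict[str, dict] = {}
    excluded_all: list = []
    for view, (bone_area, hot_area, excluded) in views.items():
        rows = {}
        for bone in hot_area:
            if bone not in table:
                raise KeyError(f"weight table has no entry for bone {bone!r}")
        for bone, area in bone_area.items():
            hot = hot_area.get(bone, 0.0)
            if hot == 0.0 and area == 0.0:
                continue
            ratio = bone_ratio(hot, area)
            weight = table[bone] if bone in table else None
            if hot > 0.0 and weight is None:
                raise KeyError(f"weight table has no entry for bone {bone!r}")
            rows[bone] = {"hotspot_area_px": hot, "bone_area_px": area,
                          "ratio": ratio,
                          "weight": weight if weight is not None else 0.0,
                          "contribution": 100.0 * (weight or 0.0) * ratio}
        excluded_all.extend({**rec, "view": view} for rec in excluded)
        breakdown[view] = rows

    per_bone: dict[str, dict] = {}
    total = 0.0
    all_bones = set(breakdown["anterior"]) | set(breakdown["posterior"])
    for bone in sorted(all_bones):
        ant = breakdown["anterior"].get(bone)
        post = breakdown["posterior"].get(bone)
        if bone in BONES_ANTERIOR_ONLY or post is None:
            contrib = ant["contribution"] if ant else 0.0
            views_used = ["anterior"] if ant else []
        elif ant is None:
            contrib = post["contribution"]
            views_used = ["posterior"]
        else:
            contrib = 0.5 * (ant["contribution"] + post["contribution"])
            views_used = ["anterior", "posterior"]
        per_bone[bone] = {
            "hotspot_area_px": {v: breakdown[v][bone]["hotspot_area_px"]
                                for v in views_used},
            "bone_area_px": {v: breakdown[v][bone]["bone_area_px"]
                             for v in views_used},
            "ratio": {v: breakdown[v][bone]["ratio"] for v in views_used},
            "weight": (ant or post)["weight"],
            "contribution": contrib,
        }
        total += contrib
    return BSIReport(per_bone=per_bone, total_bsi=float(total),
                     view_breakdown=breakdown,
                     weight_table_provenance=table.provenance,
                     unassigned_components=excluded_all)
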