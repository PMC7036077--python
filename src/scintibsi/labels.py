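"""Class-index tables shared across the pipeline.

Anterior skeleton maps carry 13 classes (background + 12 bones including
sternum and clavicle, which are hidden behind the body in the posterior
projection). Posterior maps carry 12 classes: background + the 10 bones
visible from behind + a dedicated class for the region where rib and
scapula overlap in projection.

Hot-spot maps carry 3 classes: ``others`` (background, physiological
kidney/bladder uptake), ``metastatic`` (hot spot from a bone metastatic
lesion) and ``non_malignant`` (benign hot spot: fracture, infection,
osteoarthritis).
"""

from __future__ import annotations

BONES_COMMON = (
    "skull", "cervical_vertebrae", "thoracic_vertebrae", "lumbar_vertebrae",
    "sacrum", "pelvis", "rib", "scapula", "humerus", "femur",
)
BONES_ANTERIOR_ONLY = ("sternum", "clavicle")
RIB_SCAPULA_OVERLAP = "rib_scapula_overlap"

#: anterior per-pixel classes, index = position (0 is background)
ANTERIOR_CLASSES = ("background",) + BONES_COMMON + BONES_ANTERIOR_ONLY
#: posterior per-pixel classes (0 is background, last is the overlap class)
POSTERIOR_CLASSES = ("background",) + BONES_COMMON + (RIB_SCAPULA_OVERLAP,)

N_ANTERIOR_CLASSES = len(ANTERIOR_CLASSES)   # 13
N_POSTERIOR_CLASSES = len(POSTERIOR_CLASSES)  # 12

ANTERIOR_INDEX = {name: i for i, name in enumerate(ANTERIOR_CLASSES)}
POSTERIOR_INDEX = {name: i for i, name in enumerate(POSTERIOR_CLASSES)}

# hot-spot classes
HOTSPOT_CLASSES = ("others", "metastatic", "non_malignant")
OTHERS, METASTATIC, NON_MALIGNANT = 0, 1, 2
N_HOTSPOT_CLASSES = 3


from dataclasses import dataclass  # noqa: E402
import numpy as np  # noqa: E402


@dataclass
class SkeletonLabelMap:
    """Per-view per-pixel bone class rasters (anterior 13-class, posterior
    12-class index tables above)."""

    anterior: np.ndarray
    posterior: np.ndarray

    def __post_init__(self):
        self.anterior = np.asarray(self.anterior)
        self.posterior = np.asarray(self.posterior)
        if self.anterior.max(initial=0) >= N_ANTERIOR_CLASSES:
            raise ValueError("anterior label out of range")
        if self.posterior.max(initial=0) >= N_POSTERIOR_CLASSES:
            raise ValueError("posterior label out of range")
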