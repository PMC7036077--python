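"""Raster and artifact I/O.

Count rasters are 16-bit grayscale PNG/TIFF or planar nuclear-medicine
DICOM; label maps are single-channel 8-bit indexed PNG with a JSON class
table sidecar; transforms, manifests and reports are JSON; network
checkpoints are ``.npz`` archives with a JSON config sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .networks import BtrflyConfig, BtrflyNet

__all__ = ["read_raster", "write_raster", "write_label_png", "read_label_png",
           "write_json", "read_json", "save_checkpoint", "load_checkpoint"]


def read_raster(path) -> np.ndarray:
    """Read a 2-D count raster from 16-bit PNG/TIFF or planar DICOM."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = np.asarray(ds.pixel_array)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:  # planar DICOM stacks / RGB: take the first plane
        arr = arr[0] if arr.shape[0] < arr.shape[-1] else arr[..., 0]
    return np.asarray(arr)


def write_raster(path, raster: np.ndarray) -> None:
    """Write a count raster as 16-bit PNG or TIFF (by extension)."""
    path = Path(path)
    arr = np.clip(np.rint(np.asarray(raster)), 0, np.iinfo(np.uint16).max
                  ).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def write_label_png(path, labels: np.ndarray, class_names=None) -> None:
    """Write a label map as 8-bit single-channel PNG; when ``class_names``
    is given, a ``.classes.json`` sidecar documents the index table."""
    from PIL import Image

    path = Path(path)
    arr = np.asarray(labels)
    if arr.max(initial=0) > 255:
        raise ValueError("label map does not fit 8-bit PNG")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    if class_names is not None:
        write_json(path.with_suffix(".classes.json"),
                   {str(i): name for i, name in enumerate(class_names)})


def read_label_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path)).astype(np.uint8)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def save_checkpoint(path, net: BtrflyNet) -> None:
    """Weights as ``.npz`` plus a JSON sidecar recording the architecture."""
    path = Path(path)
    np.savez_compressed(path, **net.state_dict())
    write_json(path.with_suffix(".config.json"), net.cfg.to_dict())


def load_checkpoint(path) -> BtrflyNet:
    path = Path(path)
    cfg = BtrflyConfig.from_dict(read_json(path.with_suffix(".config.json")))
    net = BtrflyNet(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        net.load_state_dict(dict(data))
    return net
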