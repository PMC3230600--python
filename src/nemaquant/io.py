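"""Image and annotation loading helpers shared by the CLI commands."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .roi import RoiSet, read_roi_archive, roi_set_from_json


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG micrograph as an 8-bit numpy array
    (HxW grayscale or HxWx3 RGB)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def save_image(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def load_roi_set(path: str | Path) -> RoiSet:
    """Read ROIs from an ImageJ .roi/.zip file or a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return roi_set_from_json(path.read_text())
    return read_roi_archive(path)
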