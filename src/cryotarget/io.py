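"""Image and JSON I/O for the targeting pipeline.

Grayscale images are accepted as MRC/CCP4 maps (modes 0/1/2, via gemmi) or
PNG/TIFF; all are returned as 2-D float arrays in (row, col) order.  Target
lists and ground truth travel as JSON.
"""

from __future__ import annotations

import json
import os

import numpy as np

__all__ = ["read_image", "write_image", "read_points_json", "write_json"]

_MRC_EXT = {".mrc", ".mrcs", ".map", ".ccp4"}
_PNG_EXT = {".png"}
_TIF_EXT = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read a grayscale image as float64 (row, col)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _MRC_EXT:
        import gemmi

        m = gemmi.read_ccp4_map(str(path))
        arr = np.array(m.grid, copy=True)
        arr = np.squeeze(arr)
        if arr.ndim == 3:  # single-section volume
            arr = arr[..., 0] if arr.shape[2] == 1 else arr[0]
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D image, got {arr.shape}")
        return np.ascontiguousarray(arr.T, dtype=np.float64)
    if ext in _PNG_EXT:
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    elif ext in _TIF_EXT:
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got {arr.shape}")
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a 2-D array: 16-bit PNG (rescaled), float TIFF, or MRC mode 2."""
    image = np.asarray(image)
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _MRC_EXT:
        import gemmi

        data3d = np.ascontiguousarray(image.T[:, :, None], dtype=np.float32)
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(data3d)
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
        return
    if ext in _TIF_EXT:
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32))
        return
    if ext in _PNG_EXT:
        from PIL import Image

        lo, hi = float(image.min()), float(image.max())
        scale = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image, float)
        Image.fromarray((scale * 65535).astype(np.uint16)).save(path)
        return
    raise ValueError(f"unsupported image format: {path}")


def read_points_json(path) -> np.ndarray:
    """Training-label file: ``{"points": [[row, col], ...]}``."""
    with open(path) as fh:
        data = json.load(fh)
    return np.asarray(data["points"], float).reshape(-1, 2)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
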