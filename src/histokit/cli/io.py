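"""Raster and JSON file I/O for the command-line pipelines."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "write_label_tiff", "read_label_tiff",
           "write_json", "read_json", "file_digest"]


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF raster as a float array (RGB kept as H x W x 3)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read raster: {path} does not exist")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - error path formatting
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(float)


def write_image(path, arr: np.ndarray):
    """Write an 8-bit PNG/TIFF raster."""
    path = Path(path)
    data = np.clip(np.asarray(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), data)
    else:
        Image.fromarray(data).save(path)


def write_label_tiff(path, labels: np.ndarray):
    """Write a label image as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def file_digest(path) -> str:
    """SHA-256 digest of a file, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
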