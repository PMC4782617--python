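"""Image ingestion: raster formats to float64 intensity matrices in [0, 1].

All downstream stages operate on 2-D ``numpy.ndarray`` matrices of float64
intensities.  Integer images are divided by their dtype maximum so that 8-bit
and 16-bit sources land on the same [0, 1] scale; color images are collapsed
to luminance before any decomposition.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import ValidationError

#: ITU-R BT.601 luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def as_image_matrix(values: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a 2-D float64 intensity matrix."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValidationError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    return arr


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) or (H, W, 4) array to luminance (H, W)."""
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3] @ LUMA_WEIGHTS
    raise ValidationError(f"cannot interpret shape {arr.shape} as an image")


def normalize_intensity(arr: np.ndarray, dtype: np.dtype | None = None) -> np.ndarray:
    """Scale an intensity array to [0, 1].

    Integer arrays are divided by the maximum of their integer type (255 for
    uint8, 65535 for uint16, ...).  Floats already in [0, 1] pass through;
    other float ranges are min-max scaled.
    """
    src_dtype = np.dtype(dtype) if dtype is not None else np.asarray(arr).dtype
    out = np.asarray(arr, dtype=np.float64)
    if np.issubdtype(src_dtype, np.integer):
        return out / np.iinfo(src_dtype).max
    lo, hi = float(out.min()), float(out.max())
    if lo >= 0.0 and hi <= 1.0:
        return out
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/PGM image file as a grayscale [0, 1] float matrix."""
    raw = iio.imread(Path(path))
    gray = to_grayscale(raw)
    return as_image_matrix(normalize_intensity(gray, dtype=raw.dtype))


def load_labeled_directory(root: str | os.PathLike):
    """Load images from ``root/normal`` (label -1) and ``root/abnormal`` (+1).

    Returns ``(images, labels, ids)``; unreadable files are skipped with a
    warning on stderr.  Raises if no usable image is found.
    """
    import sys

    root = Path(root)
    images, labels, ids = [], [], []
    for sub, label in (("normal", -1), ("abnormal", +1)):
        folder = root / sub
        if not folder.is_dir():
            continue
        for path in sorted(folder.iterdir()):
            if path.suffix.lower() not in {".png", ".tif", ".tiff", ".pgm"}:
                continue
            try:
                images.append(load_image(path))
            except Exception as exc:  # noqa: BLE001 - skip-and-report contract
                print(f"texdirect: skipping unreadable image {path}: {exc}", file=sys.stderr)
                continue
            labels.append(label)
            ids.append(f"{sub}/{path.name}")
    if not images:
        raise ValidationError(f"no usable images under {root}")
    return images, np.asarray(labels), ids
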