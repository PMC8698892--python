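"""Thin PNG/TIFF image IO wrappers used across the pipeline."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image; 4-channel inputs are reduced to RGB."""
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))
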