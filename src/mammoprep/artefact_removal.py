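"""Artefact removal for mammograms.

Scanner labels and thin bright borders are non-anatomical content that
confuses downstream analysis because their intensity is close to that of
dense tissue.  The removal chain is:

    border masking -> binary threshold -> morphological opening
    -> largest-component mask -> merge with the border-masked image

The breast is assumed to be the largest bright connected component; every
smaller bright object (labels, residual border fragments) is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "apply_border_mask",
    "binary_threshold",
    "morphological_open",
    "morphological_dilate",
    "largest_contour_mask",
    "apply_mask",
    "remove_artefacts",
]

FOREGROUND = 255


@dataclass(frozen=True)
class StructuringElement:
    """Rectangular kernel used by erosion/dilation/opening.

    ``width`` is the horizontal extent, ``height`` the vertical extent,
    matching the ``(width, height)`` tuple convention used throughout the
    pipeline configuration.
    """

    width: int
    height: int
    shape: str = "rectangle"

    def __post_init__(self) -> None:
        if self.shape != "rectangle":
            raise ValueError(f"unsupported structuring element shape: {self.shape!r}")
        if self.width < 1 or self.height < 1:
            raise ValueError("structuring element dimensions must be >= 1")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, FOREGROUND))):
        raise ValueError("mask values must be exactly 0 or 255")
    return mask.astype(np.uint8)


def apply_border_mask(image: np.ndarray, thickness: int = 5) -> np.ndarray:
    """Zero every pixel within ``thickness`` of any image edge.

    Equivalent to drawing a black rectangle of the given border thickness
    along the frame and AND-ing it with the image; the interior is
    untouched.
    """
    image = np.asarray(image)
    if thickness < 1:
        raise ValueError("border thickness must be >= 1")
    if thickness >= min(image.shape[:2]) / 2:
        raise ValueError("border thickness must be < half the smallest image dimension")
    out = image.copy()
    out[:thickness] = 0
    out[-thickness:] = 0
    out[:, :thickness] = 0
    out[:, -thickness:] = 0
    return out


def binary_threshold(image: np.ndarray, t: int = 127, m: int = 255) -> np.ndarray:
    """Global binary threshold: pixel < t -> 0, pixel >= t -> m.

    The equality case maps to the maximum value (``>= t``), which matters
    for reproducibility at the conventional t = 127.
    """
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if not 0 <= m <= 255:
        raise ValueError("maximum value must lie in [0, 255]")
    image = np.asarray(image)
    return np.where(image >= t, np.uint8(m), np.uint8(0))


def _axis_origin(k: int) -> int:
    # scipy's even-size filter window spans [-(k//2), k - 1 - k//2]; the
    # adjoint dilation needs the mirrored window, an origin shift of -1.
    return -1 if k % 2 == 0 else 0


def _erode_bool(fg: np.ndarray, se: StructuringElement) -> np.ndarray:
    return ndimage.minimum_filter(
        fg, size=(se.height, se.width), mode="constant", cval=False
    )


def _dilate_bool(fg: np.ndarray, se: StructuringElement) -> np.ndarray:
    # Mirrored window so that dilate(erode(x)) is a true opening
    # (anti-extensive and idempotent) also for even-sized kernels.
    return ndimage.maximum_filter(
        fg,
        size=(se.height, se.width),
        mode="constant",
        cval=False,
        origin=(_axis_origin(se.height), _axis_origin(se.width)),
    )


def morphological_open(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological opening: erosion followed by the adjoint dilation.

    Removes every foreground object that cannot contain the structuring
    element; pixels outside the image count as background.
    """
    mask = _check_mask(mask)
    fg = mask == FOREGROUND
    opened = _dilate_bool(_erode_bool(fg, se), se)
    return np.where(opened, np.uint8(FOREGROUND), np.uint8(0))


def morphological_dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological (Minkowski) dilation: grow foreground boundaries."""
    mask = _check_mask(mask)
    dilated = _dilate_bool(mask == FOREGROUND, se)
    return np.where(dilated, np.uint8(FOREGROUND), np.uint8(0))


def largest_contour_mask(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component, hole-filled.

    Area is the filled pixel count.  An empty mask is returned unchanged.
    """
    mask = _check_mask(mask)
    fg = mask == FOREGROUND
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return np.zeros_like(mask)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = labels == int(np.argmax(areas))
    filled = ndimage.binary_fill_holes(keep)
    return np.where(filled, np.uint8(FOREGROUND), np.uint8(0))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bitwise-AND merge: keep image pixels where the mask is foreground."""
    image = np.asarray(image)
    mask = _check_mask(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} dimensions differ"
        )
    fg = mask == FOREGROUND
    if image.ndim == 3:
        fg = fg[..., None]
    return np.where(fg, image, 0).astype(image.dtype)


def remove_artefacts(
    image: np.ndarray,
    config=None,
    return_stages: bool = False,
):
    """Full artefact-removal chain on a single grayscale image.

    border mask -> threshold -> opening -> largest component -> merge.
    Returns the cleaned image; with ``return_stages`` a dict of the
    intermediate rasters is returned as well (keys ``bordermask``,
    ``threshold``, ``open``, ``contour``).
    """
    from .config import PipelineConfig

    if config is None:
        config = PipelineConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("remove_artefacts expects a single-channel image")

    bordered = apply_border_mask(image, config.border_thickness)
    thresholded = binary_threshold(bordered, config.threshold, config.threshold_max)
    se = StructuringElement(*config.opening_kernel)
    opened = morphological_open(thresholded, se)
    contour = largest_contour_mask(opened)
    cleaned = apply_mask(bordered, contour)
    if return_stages:
        return cleaned, {
            "bordermask": bordered,
            "threshold": thresholded,
            "open": opened,
            "contour": contour,
        }
    return cleaned
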