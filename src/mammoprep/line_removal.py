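"""Removal of the bright straight line attached to the breast contour.

Some scanned mammograms carry a thin, very bright, vertical line touching
the breast region.  It cannot be removed by the artefact stage because it
is connected to the largest component.  The chain here is

    HSV conversion -> inRange brightness segmentation -> Gabor filter
    -> vertical opening -> dilation -> mask inversion -> bitwise-AND merge

The Gabor kernel acts as an oriented band-pass detector: with the default
parameters it responds strongly to thin vertical bright structures and
suppresses the interior of wide bright regions (the breast leak in the
brightness mask).  The vertical opening then discards everything without a
vertical run of at least the kernel height, the dilation widens the
detected line, and the inverted mask erases it from the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .artefact_removal import (
    FOREGROUND,
    StructuringElement,
    _check_mask,
    apply_mask,
    morphological_dilate,
    morphological_open,
)

__all__ = [
    "GaborParams",
    "IntensityRange",
    "rgb_to_hsv",
    "in_range",
    "gabor_kernel",
    "gabor_filter",
    "open_vertical",
    "dilate",
    "invert_mask",
    "remove_line",
]


@dataclass(frozen=True)
class IntensityRange:
    """Inclusive per-channel (H, S, V) bounds for colour segmentation."""

    low: tuple[int, int, int] = (0, 0, 200)
    high: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if any(lo > hi for lo, hi in zip(self.low, self.high)):
            raise ValueError("range low bound exceeds high bound")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of the real-valued Gabor kernel.

    ``ksize`` is (width, height) and must be odd in both dimensions.
    ``theta`` is the orientation, ``lambd`` the sinusoid wavelength,
    ``gamma`` the spatial aspect ratio and ``psi`` the phase offset, in
    radians unless ``psi_in_degrees`` is set.
    """

    ksize: tuple[int, int] = (5, 5)
    sigma: float = 3.0
    theta: float = math.pi
    lambd: float = math.pi / 4
    gamma: float = 0.5
    psi: float = 20.0
    psi_in_degrees: bool = False

    def __post_init__(self) -> None:
        w, h = self.ksize
        if w % 2 == 0 or h % 2 == 0:
            raise ValueError("Gabor kernel size must be odd in both dimensions")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.lambd <= 0:
            raise ValueError("lambd must be > 0")

    @property
    def psi_radians(self) -> float:
        return math.radians(self.psi) if self.psi_in_degrees else self.psi


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit HSV.

    V = max(R, G, B) and S are scaled to [0, 255]; H uses the 8-bit
    convention of half-degrees, [0, 180).  Grayscale callers must
    replicate their single channel to three channels first.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("rgb_to_hsv expects a 3-channel image")
    rgb = image.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=2)
    c = v - rgb.min(axis=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        h_deg = np.select(
            [c == 0, v == r, v == g],
            [
                0.0,
                60.0 * (g - b) / c,
                120.0 + 60.0 * (b - r) / c,
            ],
            default=240.0 + 60.0 * (r - g) / c,
        )
    h_deg = np.where(h_deg < 0, h_deg + 360.0, h_deg)
    hsv = np.empty_like(image, dtype=np.uint8)
    hsv[..., 0] = np.floor(h_deg / 2.0 + 0.5).astype(np.int64) % 180
    hsv[..., 1] = np.floor(s * 255.0 + 0.5).astype(np.uint8)
    hsv[..., 2] = v.astype(np.uint8)
    return hsv


def in_range(image: np.ndarray, rng: IntensityRange) -> np.ndarray:
    """Per-pixel conjunction: 255 iff all channels lie in [low, high]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("in_range expects a 3-channel image")
    low = np.asarray(rng.low)
    high = np.asarray(rng.high)
    inside = np.all((image >= low) & (image <= high), axis=2)
    return np.where(inside, np.uint8(FOREGROUND), np.uint8(0))


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Real part of the Gabor function sampled on the kernel grid.

    k(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambd + psi)
    with x' = x cos(theta) + y sin(theta), y' = y cos(theta) - x sin(theta).
    """
    w, h = params.ksize
    xs = np.arange(w) - w // 2
    ys = np.arange(h) - h // 2
    x, y = np.meshgrid(xs, ys)
    ct, st = math.cos(params.theta), math.sin(params.theta)
    xr = x * ct + y * st
    yr = y * ct - x * st
    envelope = np.exp(-(xr**2 + params.gamma**2 * yr**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * math.pi * xr / params.lambd + params.psi_radians)
    return envelope * carrier


def gabor_filter(mask1: np.ndarray, params: GaborParams) -> np.ndarray:
    """Correlate a binary mask with the Gabor kernel and re-binarize.

    The raw correlation (reflection padding) is clipped to [0, 255] and
    thresholded at 127 so that the result remains a {0, 255} mask.
    """
    mask1 = _check_mask(mask1)
    kernel = gabor_kernel(params)
    response = ndimage.correlate(mask1.astype(np.float64), kernel, mode="reflect")
    clipped = np.clip(response, 0.0, 255.0)
    return np.where(clipped >= 127.0, np.uint8(FOREGROUND), np.uint8(0))


def open_vertical(mask2: np.ndarray, kernel: tuple[int, int] = (1, 30)) -> np.ndarray:
    """Opening with a 1-wide, 30-tall rectangle: keep only vertical runs
    of at least the kernel height."""
    return morphological_open(mask2, StructuringElement(*kernel))


def dilate(mask3: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Dilation (default 5x5) widening the detected line."""
    if se is None:
        se = StructuringElement(5, 5)
    return morphological_dilate(mask3, se)


def invert_mask(mask4: np.ndarray) -> np.ndarray:
    """Per-pixel complement 255 - value (an involution on masks)."""
    mask4 = _check_mask(mask4)
    return (FOREGROUND - mask4.astype(np.int16)).astype(np.uint8)


def remove_line(
    image: np.ndarray,
    config=None,
    return_stages: bool = False,
):
    """Detect and erase the bright attached vertical line.

    Accepts a grayscale (artefact-removed) image; the HSV step sees the
    gray value replicated to three channels.  Pixels under the dilated
    detected line are set to 0, everything else is untouched.  With
    ``return_stages`` the intermediate masks 1-5 are returned as a dict.
    """
    from .config import PipelineConfig

    if config is None:
        config = PipelineConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("remove_line expects a single-channel image")

    rgb = np.repeat(image[..., None], 3, axis=2)
    hsv = rgb_to_hsv(rgb)
    mask1 = in_range(hsv, IntensityRange(config.inrange_low, config.inrange_high))
    mask2 = gabor_filter(mask1, config.gabor_params())
    mask3 = open_vertical(mask2, config.vertical_kernel)
    mask4 = dilate(mask3, StructuringElement(*config.dilation_kernel))
    mask5 = invert_mask(mask4)
    merged = apply_mask(image, mask5)
    if return_stages:
        return merged, {
            "mask1": mask1,
            "mask2": mask2,
            "mask3": mask3,
            "mask4": mask4,
            "mask5": mask5,
        }
    return merged
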