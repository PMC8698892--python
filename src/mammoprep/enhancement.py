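"""Lesion-visibility enhancement: gamma, double CLAHE, Green-Fire-Blue.

Dense breast tissue and lesions occupy a narrow bright intensity band, so
plain display of a mammogram hides the lesion.  The enhancement chain

    gamma correction (g = 2.0) -> CLAHE -> CLAHE -> Green-Fire-Blue LUT

first lifts the mid-tones, then equalizes contrast locally (twice, which
stretches lesion-vs-tissue differences without the over-amplification a
third pass would cause), and finally recolors the grayscale result so that
background, dense tissue and lesion fall into distinct hue bands
(black -> blue -> green -> yellow/white).

The CLAHE implementation follows the classic tile scheme: per-tile
histogram, clipping at ``clip_limit_norm`` times the average bin count,
uniform redistribution of the excess, per-tile equalization mapping, and
bilinear interpolation between the four surrounding tile mappings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GammaParams",
    "CLAHEParams",
    "gamma_correct",
    "clahe",
    "double_clahe",
    "builtin_gfb_lut",
    "identity_lut",
    "load_lut",
    "green_fire_blue",
    "enhance",
]


@dataclass(frozen=True)
class GammaParams:
    """Gamma value g of the power-law map o = m^(1/g) on [0, 1]."""

    g: float = 2.0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("gamma value must be > 0")


@dataclass(frozen=True)
class CLAHEParams:
    clip_limit_norm: float | None = 1.0  # None disables clipping
    tile_grid: tuple[int, int] = (8, 8)  # (tiles_x, tiles_y)
    gray_levels: int = 256

    def __post_init__(self) -> None:
        tx, ty = self.tile_grid
        if tx < 1 or ty < 1:
            raise ValueError("tile counts must be >= 1")
        if self.clip_limit_norm is not None and not np.isinf(self.clip_limit_norm):
            if self.clip_limit_norm <= 0:
                raise ValueError("clip limit must be > 0")


def gamma_correct(image: np.ndarray, params: GammaParams | float = GammaParams()) -> np.ndarray:
    """Power-law brightness map o = 255 * (m / 255)^(1/g).

    Monotone non-decreasing with fixed points at 0 and 255; results are
    rounded half-up for determinism.  g > 1 brightens the mid-tones.
    """
    if isinstance(params, (int, float)):
        params = GammaParams(float(params))
    image = np.asarray(image)
    lut = np.floor(255.0 * (np.arange(256) / 255.0) ** (1.0 / params.g) + 0.5)
    return lut.astype(np.uint8)[image]


def _tile_mapping(tile: np.ndarray, params: CLAHEParams) -> np.ndarray:
    """Equalization LUT for one tile: clipped histogram -> scaled CDF."""
    n_g = params.gray_levels
    hist = np.bincount(tile.ravel(), minlength=n_g).astype(np.int64)
    npix = tile.size
    if params.clip_limit_norm is not None and not np.isinf(params.clip_limit_norm):
        n_avg = npix / n_g
        clip = max(1, int(params.clip_limit_norm * n_avg))
        excess = int(np.sum(np.maximum(hist - clip, 0)))
        hist = np.minimum(hist, clip)
        if excess:
            # uniform pass, then leftovers round-robin low-to-high
            hist += excess // n_g
            hist[: excess % n_g] += 1
    cdf = np.cumsum(hist)
    return np.floor(cdf * (n_g - 1) / npix + 0.5).astype(np.uint8)


def clahe(image: np.ndarray, params: CLAHEParams = CLAHEParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on one channel.

    The image is divided into ``tile_grid`` tiles (reflection-padded to a
    multiple of the grid when needed); each pixel is mapped through a
    bilinear blend of the four surrounding tile mappings, which removes
    the artificial tile boundaries that per-tile equalization would leave.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("clahe expects a single-channel image")
    if image.dtype != np.uint8:
        raise ValueError("clahe expects an 8-bit image")
    tx, ty = params.tile_grid
    h, w = image.shape
    th = -(-h // ty)  # ceil
    tw = -(-w // tx)
    padded = np.pad(image, ((0, th * ty - h), (0, tw * tx - w)), mode="reflect")

    luts = np.empty((ty, tx, params.gray_levels), dtype=np.uint8)
    for i in range(ty):
        for j in range(tx):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_mapping(tile, params)

    # blend coordinates relative to tile centers, clamped at the frame
    rows = (np.arange(h) - (th - 1) / 2.0) / th
    cols = (np.arange(w) - (tw - 1) / 2.0) / tw
    i0 = np.clip(np.floor(rows).astype(int), 0, ty - 1)
    i1 = np.clip(i0 + 1, 0, ty - 1)
    j0 = np.clip(np.floor(cols).astype(int), 0, tx - 1)
    j1 = np.clip(j0 + 1, 0, tx - 1)
    fy = np.clip(rows - np.floor(rows), 0.0, 1.0)
    fy[rows < 0] = 0.0
    fy[rows > ty - 1] = 1.0
    fx = np.clip(cols - np.floor(cols), 0.0, 1.0)
    fx[cols < 0] = 0.0
    fx[cols > tx - 1] = 1.0

    img = image[:h, :w]
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    v00 = luts[i0[:, None], j0[None, :], img].astype(np.float64)
    v01 = luts[i0[:, None], j1[None, :], img].astype(np.float64)
    v10 = luts[i1[:, None], j0[None, :], img].astype(np.float64)
    v11 = luts[i1[:, None], j1[None, :], img].astype(np.float64)
    wy = fy[:, None]
    wx = fx[None, :]
    out = (
        (1 - wy) * (1 - wx) * v00
        + (1 - wy) * wx * v01
        + wy * (1 - wx) * v10
        + wy * wx * v11
    )
    return np.floor(out + 0.5).astype(np.uint8)


def double_clahe(image: np.ndarray, params: CLAHEParams = CLAHEParams()) -> np.ndarray:
    """Exactly two CLAHE passes with the same parameters."""
    return clahe(clahe(image, params), params)


# Control points of the built-in Green-Fire-Blue table.  Linear ramps per
# channel give the black -> blue -> green -> yellow/white progression.
_GFB_CONTROL = {
    "R": [(0, 0), (150, 0), (235, 255), (255, 255)],
    "G": [(0, 0), (180, 255), (255, 255)],
    "B": [(0, 0), (100, 255), (200, 0), (240, 0), (255, 200)],
}


def builtin_gfb_lut() -> np.ndarray:
    """256 x 3 Green-Fire-Blue lookup table (RGB, uint8)."""
    idx = np.arange(256)
    lut = np.empty((256, 3), dtype=np.uint8)
    for ch, name in enumerate("RGB"):
        pts = _GFB_CONTROL[name]
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        lut[:, ch] = np.floor(np.interp(idx, xs, ys) + 0.5).astype(np.uint8)
    return lut


def identity_lut() -> np.ndarray:
    """Gray ramp (R = G = B = index); recoloring with it replicates channels."""
    ramp = np.arange(256, dtype=np.uint8)
    return np.stack([ramp, ramp, ramp], axis=1)


def _validate_lut(lut: np.ndarray) -> np.ndarray:
    lut = np.asarray(lut)
    if lut.shape != (256, 3):
        raise ValueError("LUT must have exactly 256 RGB entries")
    if lut.min() < 0 or lut.max() > 255:
        raise ValueError("LUT values must lie in [0, 255]")
    return lut.astype(np.uint8)


def load_lut(path: str | Path) -> np.ndarray:
    """Read a lookup table from disk.

    Supports the ImageJ binary ``.lut`` layout (768 bytes: 256 R, 256 G,
    256 B) and a 256-row CSV dialect (columns R, G, B, optional header).
    """
    path = Path(path)
    if path.suffix.lower() == ".lut":
        raw = path.read_bytes()
        if len(raw) != 768:
            raise ValueError(f"ImageJ .lut file must be 768 bytes, got {len(raw)}")
        arr = np.frombuffer(raw, dtype=np.uint8).reshape(3, 256)
        return arr.T.copy()
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh):
            if not rec or not rec[0].strip().lstrip("-").isdigit():
                continue  # header or blank
            rows.append([int(v) for v in rec[:3]])
    return _validate_lut(np.array(rows))


def green_fire_blue(image: np.ndarray, lut: np.ndarray | None = None) -> np.ndarray:
    """Recolor a grayscale image through a 256-entry RGB lookup table."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("green_fire_blue expects a single-channel image")
    lut = builtin_gfb_lut() if lut is None else _validate_lut(lut)
    return lut[image]


def as_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an image to one channel.

    Gray-in-RGB inputs (all channels equal) return the first channel;
    genuine colour inputs are reduced to rounded luminance.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        if np.array_equal(image[..., 0], image[..., 1]) and np.array_equal(
            image[..., 0], image[..., 2]
        ):
            return image[..., 0]
        lum = 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
        return np.floor(lum + 0.5).astype(np.uint8)
    raise ValueError("expected a 2-D or 3-channel image")


def enhance(
    image: np.ndarray,
    config=None,
    lut: np.ndarray | None = None,
    return_stages: bool = False,
):
    """Full enhancement chain on a (line-removed) image.

    gamma -> CLAHE x ``clahe_passes`` -> LUT recoloring.  Returns the
    3-channel recolored image; with ``return_stages`` also the grayscale
    intermediates (keys ``gamma``, ``clahe1``, ``clahe2``, ``gfb``).
    """
    from .config import PipelineConfig

    if config is None:
        config = PipelineConfig()
    gray = as_gray(image)
    stages: dict[str, np.ndarray] = {}
    out = gamma_correct(gray, GammaParams(config.gamma_value))
    stages["gamma"] = out
    params = CLAHEParams(config.clahe_clip, config.clahe_tiles)
    for i in range(config.clahe_passes):
        out = clahe(out, params)
        stages[f"clahe{i + 1}"] = out
    if lut is None and config.lut_path is not None:
        lut = load_lut(config.lut_path)
    recolored = green_fire_blue(out, lut)
    stages["gfb"] = recolored
    if return_stages:
        return recolored, stages
    return recolored
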