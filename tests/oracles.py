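"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes an operation by a different route than the package
(explicit loops, shifted copies, pair counting) so that agreement is
meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np


def erode_bruteforce(fg: np.ndarray, width: int, height: int) -> np.ndarray:
    """Binary erosion as an AND over all shifted copies (outside = 0)."""
    h, w = fg.shape
    out = np.ones_like(fg, dtype=bool)
    for dy in range(-(height // 2), height - height // 2):
        for dx in range(-(width // 2), width - width // 2):
            shifted = np.zeros_like(fg, dtype=bool)
            ys = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, -dx), min(w, w - dx))
            shifted[ys, xs] = fg[
                max(0, dy) : min(h, h + dy), max(0, dx) : min(w, w + dx)
            ]
            out &= shifted
    return out


def dilate_bruteforce(fg: np.ndarray, width: int, height: int) -> np.ndarray:
    """Binary dilation as an OR over all shifted copies."""
    h, w = fg.shape
    out = np.zeros_like(fg, dtype=bool)
    for dy in range(-(height // 2), height - height // 2):
        for dx in range(-(width // 2), width - width // 2):
            shifted = np.zeros_like(fg, dtype=bool)
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            shifted[ys, xs] = fg[
                max(0, -dy) : min(h, h - dy), max(0, -dx) : min(w, w - dx)
            ]
            out |= shifted
    return out


def open_bruteforce(fg: np.ndarray, width: int, height: int) -> np.ndarray:
    """Opening = erosion then Minkowski dilation with the same element."""
    return dilate_bruteforce(erode_bruteforce(fg, width, height), width, height)


def largest_component_bruteforce(fg: np.ndarray) -> np.ndarray:
    """Largest 8-connected component by depth-first flood fill."""
    h, w = fg.shape
    seen = np.zeros_like(fg, dtype=bool)
    best: list[tuple[int, int]] = []
    for sy in range(h):
        for sx in range(w):
            if not fg[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            if len(comp) > len(best):
                best = comp
    out = np.zeros_like(fg, dtype=bool)
    for y, x in best:
        out[y, x] = True
    return out


def fill_holes_bruteforce(fg: np.ndarray) -> np.ndarray:
    """Foreground plus every background region not reachable from the frame."""
    h, w = fg.shape
    outside = np.zeros_like(fg, dtype=bool)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and not fg[y, x]
    ]
    for y, x in stack:
        outside[y, x] = True
    while stack:
        y, x = stack.pop()
        for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            if 0 <= ny < h and 0 <= nx < w and not fg[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    return fg | ~outside


def hsv_pixel(r: int, g: int, b: int) -> tuple[int, int, int]:
    """Scalar RGB -> HSV conversion with 8-bit scaling (H in half-degrees)."""
    v = max(r, g, b)
    mn = min(r, g, b)
    c = v - mn
    s = 0.0 if v == 0 else c / v
    if c == 0:
        h = 0.0
    elif v == r:
        h = 60.0 * (g - b) / c
    elif v == g:
        h = 120.0 + 60.0 * (b - r) / c
    else:
        h = 240.0 + 60.0 * (r - g) / c
    if h < 0:
        h += 360.0
    return (int(math.floor(h / 2.0 + 0.5)) % 180, int(math.floor(s * 255.0 + 0.5)), v)


def gabor_value(x, y, sigma, theta, lambd, gamma, psi) -> float:
    """Scalar evaluation of the real Gabor function at one grid point."""
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = y * math.cos(theta) - x * math.sin(theta)
    envelope = math.exp(-(xr**2 + gamma**2 * yr**2) / (2.0 * sigma**2))
    return envelope * math.cos(2.0 * math.pi * xr / lambd + psi)


def ssim_direct(a: np.ndarray, b: np.ndarray, win_size: int = 11, sigma: float = 1.5) -> float:
    """SSIM by direct evaluation of the luminance-contrast-structure
    product over Gaussian-weighted sliding windows (valid region)."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    half = win_size // 2
    ax = np.arange(win_size) - half
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    win = np.outer(g1, g1)
    win /= win.sum()
    c1 = (0.01 * 255) ** 2
    c2 = (0.03 * 255) ** 2
    h, w = a.shape
    vals = []
    for y in range(half, h - half):
        for x in range(half, w - half):
            pa = a[y - half : y + half + 1, x - half : x + half + 1]
            pb = b[y - half : y + half + 1, x - half : x + half + 1]
            mu_a = float((win * pa).sum())
            mu_b = float((win * pb).sum())
            var_a = float((win * (pa - mu_a) ** 2).sum())
            var_b = float((win * (pb - mu_b) ** 2).sum())
            cov = float((win * (pa - mu_a) * (pb - mu_b)).sum())
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(vals))


def auc_pair_counting(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a random positive scores
    above a random negative (ties count one half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def global_hist_eq(image: np.ndarray) -> np.ndarray:
    """Plain global histogram equalization: round(cdf(v) * 255 / npix)."""
    counts = np.array([(image == v).sum() for v in range(256)], dtype=np.int64)
    cdf = np.cumsum(counts)
    lut = np.floor(cdf * 255.0 / image.size + 0.5).astype(np.uint8)
    return lut[image]
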