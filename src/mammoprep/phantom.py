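"""Seeded phantom mammograms with ground-truth masks.

Real screening mammograms carry a characteristic set of nuisances: a
bright label near a corner, a thin white border along an image edge, and
sometimes a bright straight line touching the breast contour.  The
phantom generator emulates exactly these features on a simple anatomical
model — a textured half-elliptical breast flush against one image edge, a
lesion (a mass blob or a cluster of calcification speckles) embedded in
the dense tissue — and returns per-feature ground-truth masks so that
every removal stage can be scored against what was actually stamped.

Intensity design (8-bit):

* background noise stays below 30;
* dense tissue occupies [130, 195], so a global threshold at 127 segments
  the breast but brightness segmentation at 200 ignores it;
* labels, borders and the attached line are stamped at >= 200, the band
  the artefact and line stages are tuned to.

The breast's flat side sits just inside the standard 5-pixel border band
(a thin dark film margin separates it from the edge), so border masking
removes border artefacts without eating into the anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_image

__all__ = [
    "CLASSES",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "add_gaussian_noise",
    "generate_dataset",
    "derive_seed",
]

CLASSES = ("BC", "BM", "MC", "MM")
EDGES = ("top", "left", "bottom", "right")

_FG = 255
_CHEST_MARGIN = 6  # dark film margin between image edge and chest wall


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; the seed fixes every random draw."""

    size: tuple[int, int] = (224, 224)  # (height, width)
    class_label: str = "BM"
    has_corner_label: bool = False
    has_border_line: bool = False
    border_edge: str = "top"
    has_attached_line: bool = False
    lesion_kind: str | None = None  # derived from class when None
    tissue_density: float = 0.7
    breast_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 64 or w < 64:
            raise ValueError("phantom dimensions must be >= 64")
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.border_edge not in EDGES:
            raise ValueError(f"unknown border edge {self.border_edge!r}")
        if self.breast_side not in ("left", "right"):
            raise ValueError("breast side must be 'left' or 'right'")
        if self.lesion_kind is not None and self.lesion_kind not in (
            "mass-blob",
            "calcification-speckles",
        ):
            raise ValueError(f"unknown lesion kind {self.lesion_kind!r}")
        if not 0.0 <= self.tissue_density <= 1.0:
            raise ValueError("tissue density must lie in [0, 1]")

    @property
    def resolved_lesion_kind(self) -> str:
        if self.lesion_kind is not None:
            return self.lesion_kind
        return "calcification-speckles" if self.class_label in ("BC", "MC") else "mass-blob"


@dataclass
class PhantomTruth:
    """Ground-truth geometry stamped into a phantom, as {0, 255} masks."""

    breast_mask: np.ndarray
    lesion_mask: np.ndarray
    artefact_mask: np.ndarray  # corner label + border line
    line_mask: np.ndarray  # attached vertical line


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-frequency texture field normalized to [-1, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(raw).max()
    return raw / peak if peak > 0 else raw


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom image and its truth masks.

    Same spec (including seed) -> bit-identical output.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.clip(np.abs(rng.normal(8.0, 5.0, (h, w))), 0, 28)

    # --- breast: half-ellipse, flat side at the left chest wall ----------
    a = rng.uniform(0.50, 0.60) * w  # horizontal semi-axis
    b = rng.uniform(0.38, 0.45) * h  # vertical semi-axis
    cy = h / 2.0 + rng.uniform(-0.03, 0.03) * h
    x0 = _CHEST_MARGIN
    yy, xx = np.mgrid[0:h, 0:w]
    norm = ((xx - x0) / a) ** 2 + ((yy - cy) / b) ** 2
    breast = (xx >= x0) & (norm <= 1.0)

    tissue = 150.0 + 45.0 * spec.tissue_density * _smooth_noise(rng, (h, w), 8.0)
    tissue = np.clip(tissue, 130.0, 195.0)
    img[breast] = tissue[breast]

    lesion_mask = np.zeros((h, w), dtype=bool)
    line_mask = np.zeros((h, w), dtype=bool)
    artefact_mask = np.zeros((h, w), dtype=bool)

    # --- attached bright vertical line inside the breast contour ---------
    line_col = None
    if spec.has_attached_line:
        frac = rng.uniform(0.45, 0.60)
        line_col = int(x0 + frac * a)
        half_h = b * np.sqrt(max(1.0 - frac**2, 0.0))
        r0 = max(int(cy - half_h) + 3, 0)
        r1 = min(int(cy + half_h) - 3, h - 1)
        width = 3
        c0 = line_col - width // 2
        line_mask[r0 : r1 + 1, c0 : c0 + width] = True
        line_mask &= breast
        img[line_mask] = rng.uniform(225.0, 245.0)

    # --- lesion, kept inside the breast and clear of the line column ------
    # with a line at 0.45-0.60 of the semi-axis, a lesion left of 0.24 of
    # it stays >= ~23 px away, beyond the Gabor + dilation reach
    kind = spec.resolved_lesion_kind
    fx = rng.uniform(0.12, 0.24) if line_col is not None else rng.uniform(0.15, 0.50)
    fy = rng.uniform(-0.40, 0.40)
    lx = x0 + fx * a
    ly = cy + fy * b
    d = np.hypot(xx - lx, yy - ly)
    # lesions sit only modestly above the dense-tissue band: masses and
    # calcifications embedded in dense tissue are low-contrast, which is
    # what makes the enhancement stage necessary in the first place
    if kind == "mass-blob":
        r = rng.uniform(6.0, 9.0)
        bump = np.exp(-((d / r) ** 2) * 1.5)
        lesion_mask = d <= r
        region = d <= 1.5 * r
        img[region] = np.maximum(
            img[region], np.minimum(tissue[region] + 28.0 * bump[region], 199.0)
        )
    else:
        n_dots = rng.integers(10, 18)
        for _ in range(int(n_dots)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 12.0)
            dx, dy = lx + rad * np.cos(ang), ly + rad * np.sin(ang)
            dot = np.hypot(xx - dx, yy - dy) <= rng.uniform(1.0, 2.0)
            lesion_mask |= dot
            img[dot] = np.minimum(tissue[dot] + rng.uniform(13.0, 21.0), 199.0)
    lesion_mask &= breast
    if spec.has_attached_line:
        lesion_mask &= ~line_mask

    # --- corner label (small, bright, disconnected from the breast) ------
    if spec.has_corner_label:
        lw = int(rng.integers(12, 22))
        lh = int(rng.integers(9, 16))
        top = bool(rng.integers(0, 2))
        r0 = rng.integers(8, 20) if top else h - lh - rng.integers(8, 20)
        c0 = w - lw - rng.integers(8, 24)
        label = np.zeros((h, w), dtype=bool)
        label[r0 : r0 + lh, c0 : c0 + lw] = True
        label &= ~breast
        artefact_mask |= label
        img[label] = 255.0

    # --- thin white border line along one image edge ----------------------
    if spec.has_border_line:
        t = int(rng.integers(2, 4))
        off = int(rng.integers(0, 2))
        border = np.zeros((h, w), dtype=bool)
        if spec.border_edge == "top":
            border[off : off + t, :] = True
        elif spec.border_edge == "bottom":
            border[h - off - t : h - off, :] = True
        elif spec.border_edge == "left":
            border[:, off : off + t] = True
        else:
            border[:, w - off - t : w - off] = True
        border &= ~breast
        artefact_mask |= border
        img[border] = 255.0

    image = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    masks = [breast, lesion_mask, artefact_mask, line_mask]
    if spec.breast_side == "right":
        image = image[:, ::-1].copy()
        masks = [m[:, ::-1].copy() for m in masks]

    to_mask = lambda m: np.where(m, np.uint8(_FG), np.uint8(0))
    truth = PhantomTruth(*(to_mask(m) for m in masks))
    return image, truth


def add_gaussian_noise(image: np.ndarray, variance: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise with the given variance on the [0, 1]
    intensity scale, then clip to [0, 255] and re-quantize."""
    if variance <= 0:
        raise ValueError("noise variance must be > 0")
    image = np.asarray(image)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(variance), image.shape) * 255.0
    noisy = np.floor(image.astype(np.float64) + noise + 0.5)
    return np.clip(noisy, 0, 255).astype(np.uint8)


def lesion_contrast(image: np.ndarray, truth: PhantomTruth) -> float:
    """Lesion-to-surround contrast against the ground-truth geometry.

    Mean intensity inside the lesion mask minus the mean over a ring of
    surrounding breast tissue (2-10 px outside the lesion, excluding the
    attached-line neighbourhood).  Local by construction: this is the
    contrast a reader relies on to spot the lesion against adjacent
    tissue.
    """
    image = np.asarray(image, dtype=np.float64)
    les = truth.lesion_mask == _FG
    breast = truth.breast_mask == _FG
    if not les.any():
        raise ValueError("phantom has no lesion")
    inner = ndimage.binary_dilation(les, iterations=2)
    outer = ndimage.binary_dilation(les, iterations=10)
    ring = outer & ~inner & breast
    line = truth.line_mask == _FG
    if line.any():
        ring &= ~ndimage.binary_dilation(line, iterations=6)
    return float(image[les].mean() - image[ring].mean())


def derive_seed(dataset_seed: int, index: int) -> int:
    """Per-image seed: mix (dataset seed, row index) through a seed
    sequence and reduce below 2**31."""
    state = np.random.SeedSequence([dataset_seed, index]).generate_state(1)[0]
    return int(state % (2**31))


def generate_dataset(
    counts_per_class: dict[str, int],
    seed: int,
    out_dir: str | Path,
    write_truth: bool = True,
    artefact_probs: tuple[float, float, float] = (0.6, 0.4, 0.5),
) -> pd.DataFrame:
    """Write a seeded phantom dataset and return its manifest.

    One row per image with columns ``path, class, split, seed``; the split
    column starts as ``unassigned``.  Artefact flags are drawn per image
    (label / border / attached-line probabilities given by
    ``artefact_probs``) from that image's own seed, so the dataset mirrors
    a collection in which artefacts appear across all classes.
    """
    for cls, n in counts_per_class.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        if n < 0:
            raise ValueError("class counts must be >= 0")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    if write_truth:
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)

    rows = []
    index = 0
    for cls in CLASSES:
        for k in range(counts_per_class.get(cls, 0)):
            img_seed = derive_seed(seed, index)
            flag_rng = np.random.default_rng(img_seed + 1)
            p_label, p_border, p_line = artefact_probs
            spec = PhantomSpec(
                class_label=cls,
                has_corner_label=bool(flag_rng.random() < p_label),
                has_border_line=bool(flag_rng.random() < p_border),
                border_edge=EDGES[int(flag_rng.integers(0, 4))],
                has_attached_line=bool(flag_rng.random() < p_line),
                seed=img_seed,
            )
            image, truth = generate_phantom(spec)
            path = out_dir / "images" / f"{cls}_{k:05d}.png"
            write_image(path, image)
            if write_truth:
                for name, mask in (
                    ("breast", truth.breast_mask),
                    ("lesion", truth.lesion_mask),
                    ("artefact", truth.artefact_mask),
                    ("line", truth.line_mask),
                ):
                    write_image(out_dir / "truth" / f"{cls}_{k:05d}_{name}.png", mask)
            rows.append(
                {"path": str(path), "class": cls, "split": "unassigned", "seed": img_seed}
            )
            index += 1

    manifest = pd.DataFrame(rows, columns=["path", "class", "split", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
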