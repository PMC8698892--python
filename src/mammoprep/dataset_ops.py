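"""Dataset bookkeeping: curation, 8x augmentation, stratified splitting.

The augmentation applies seven deterministic geometric transforms and
keeps the original, multiplying the dataset by exactly eight while
preserving per-class proportions.  The split assigns, per class,
``floor(test_fraction * n)`` rows to test and ``floor(val_fraction * n) + 1``
to validation, the remainder to training — the per-class rule consistent
with a 70:10:20 train/validation/test split where the validation set is
kept slightly smaller than a straight 10% would leave the training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .io import read_image, write_image

__all__ = [
    "CLASSES",
    "SplitRule",
    "TRANSFORMS",
    "curate",
    "rotate",
    "augment",
    "split",
    "split_counts",
]

logger = logging.getLogger(__name__)

CLASSES = ("BC", "BM", "MC", "MM")
MANIFEST_COLUMNS = ["path", "class", "split", "source", "transform"]


@dataclass(frozen=True)
class SplitRule:
    """Per-class count rule for the stratified train/val/test split."""

    test_fraction: float = 0.20
    val_fraction: float = 0.10
    val_extra: int = 1  # floor(val_fraction * n) + val_extra rows go to val
    shuffle_seed: int = 0

    def counts(self, n: int) -> tuple[int, int, int]:
        """(train, val, test) counts for a class of size n."""
        n_test = int(np.floor(self.test_fraction * n))
        n_val = int(np.floor(self.val_fraction * n)) + self.val_extra
        n_train = n - n_test - n_val
        if n_train < 0:
            raise ValueError(f"split rule infeasible for class size {n}")
        return n_train, n_val, n_test


def curate(manifest: pd.DataFrame, removals: list[str]) -> pd.DataFrame:
    """Drop the given rows (manually identified blank/artefact-only images)."""
    known = set(manifest["path"])
    for path in removals:
        if path not in known:
            raise ValueError(f"cannot remove unknown manifest path: {path}")
    return manifest[~manifest["path"].isin(set(removals))].reset_index(drop=True)


def rotate(image: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate about the image center, bilinear, zero fill, same canvas."""
    if abs(degrees) >= 360:
        raise ValueError("rotation angle must satisfy |degrees| < 360")
    image = np.asarray(image)
    out = _sk_rotate(
        image.astype(np.float64),
        degrees,
        resize=False,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _vflip(img: np.ndarray) -> np.ndarray:
    return img[::-1].copy()


def _hflip(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1].copy()


# the seven augmentations; "rot30_hflip" means rotate first, then flip
TRANSFORMS: dict[str, callable] = {
    "vflip": _vflip,
    "hflip": _hflip,
    "hvflip": lambda img: _vflip(_hflip(img)),
    "rot30": lambda img: rotate(img, 30),
    "rot30_hflip": lambda img: _hflip(rotate(img, 30)),
    "rot-30": lambda img: rotate(img, -30),
    "rot-30_hflip": lambda img: _hflip(rotate(img, -30)),
}


def augment(manifest: pd.DataFrame, out_dir: str | Path) -> pd.DataFrame:
    """Write the original plus seven transformed copies of every image.

    The returned manifest has exactly 8x the input rows; class labels are
    inherited and every augmented row records its source image and
    transform.  Unreadable images are skipped (with a log entry) rather
    than aborting the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for src_path, cls in zip(manifest["path"], manifest["class"]):
        try:
            image = read_image(src_path)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable image %s: %s", src_path, exc)
            continue
        stem = Path(src_path).stem
        outputs = {"original": image}
        for name, fn in TRANSFORMS.items():
            outputs[name] = fn(image)
        for name, img in outputs.items():
            path = out_dir / f"{stem}_{name}.png"
            write_image(path, img)
            rows.append(
                {
                    "path": str(path),
                    "class": cls,
                    "split": "unassigned",
                    "source": str(src_path),
                    "transform": name,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def split(manifest: pd.DataFrame, rule: SplitRule = SplitRule()) -> pd.DataFrame:
    """Stratified, seeded train/val/test assignment.

    Per class the rows are shuffled by ``shuffle_seed``; the first
    ``floor(test_fraction * n)`` go to test, the next
    ``floor(val_fraction * n) + val_extra`` to validation, the rest to
    training.  The three partitions are disjoint and exhaustive.
    """
    if (manifest["split"] != "unassigned").any():
        raise ValueError("split expects all rows unassigned")
    out = manifest.copy()
    rng = np.random.default_rng(rule.shuffle_seed)
    for cls in sorted(out["class"].unique()):
        idx = out.index[out["class"] == cls].to_numpy()
        n = len(idx)
        if n < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        n_train, n_val, n_test = rule.counts(n)
        perm = rng.permutation(n)
        shuffled = idx[perm]
        out.loc[shuffled[:n_test], "split"] = "test"
        out.loc[shuffled[n_test : n_test + n_val], "split"] = "val"
        out.loc[shuffled[n_test + n_val :], "split"] = "train"
    return out


def split_counts(manifest: pd.DataFrame) -> pd.Series:
    """Row counts per split partition."""
    return manifest["split"].value_counts()
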