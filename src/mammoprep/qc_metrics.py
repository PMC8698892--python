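"""Verification metrics: MSE, PSNR, SSIM, RMSE and histograms.

Preprocessing must not degrade image content; these reference metrics
compare an original image against its processed counterpart.  Colour
outputs (the LUT-recolored stage) are reduced to luminance first so the
comparison stays on one intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .enhancement import as_gray

__all__ = ["QCRecord", "mse", "psnr", "ssim", "rmse", "histogram", "qc_report"]

logger = logging.getLogger(__name__)

MAX_INTENSITY = 255.0


@dataclass
class QCRecord:
    image: str
    mse: float
    psnr_db: float
    ssim: float
    rmse: float


def _pair(original: np.ndarray, processed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = as_gray(original)
    b = as_gray(processed)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def mse(original: np.ndarray, processed: np.ndarray) -> float:
    """Mean squared per-pixel difference on the [0, 255] scale."""
    a, b = _pair(original, processed)
    diff = a.astype(np.float64) - b.astype(np.float64)
    return float(np.mean(diff**2))


def psnr(original: np.ndarray, processed: np.ndarray) -> float:
    """Peak signal-to-noise ratio, 10 log10(255^2 / MSE) dB.

    Identical images give +inf (noise-free).
    """
    err = mse(original, processed)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(MAX_INTENSITY**2 / err))


def ssim(
    original: np.ndarray,
    processed: np.ndarray,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Structural similarity index, mean over Gaussian-weighted windows.

    Uses the standard 11x11 Gaussian window (sigma 1.5) and stabilizers
    c1 = (0.01*255)^2, c2 = (0.03*255)^2; 1 means structurally identical.
    """
    a, b = _pair(original, processed)
    if min(a.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}x{win_size} SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=255,
            K1=0.01,
            K2=0.03,
        )
    )


def rmse(original: np.ndarray, processed: np.ndarray, normalized: bool = False) -> float:
    """Root of the MSE; ``normalized`` divides by 255 for a [0, 1] scale."""
    value = float(np.sqrt(mse(original, processed)))
    return value / MAX_INTENSITY if normalized else value


def histogram(image: np.ndarray) -> np.ndarray:
    """256-bin intensity counts, shape (256,) or (channels, 256)."""
    image = np.asarray(image)
    if image.ndim == 2:
        return np.bincount(image.ravel(), minlength=256)[:256]
    if image.ndim == 3:
        return np.stack(
            [np.bincount(image[..., c].ravel(), minlength=256)[:256] for c in range(image.shape[2])]
        )
    raise ValueError("expected a 2-D or 3-D image")


def qc_report(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    out: str | Path,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Write one CSV row of metrics per (original, processed) pair.

    Histograms for both members of each pair are written as side-car CSVs
    next to the report.  Per-file IO failures are logged and skipped so a
    long run is never aborted by one bad pair.
    """
    if not pairs:
        raise ValueError("qc_report needs at least one image pair")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    if names is None:
        names = [f"pair_{i:04d}" for i in range(len(pairs))]

    records = []
    for name, (orig, proc) in zip(names, pairs):
        rec = QCRecord(
            image=name,
            mse=mse(orig, proc),
            psnr_db=psnr(orig, proc),
            ssim=ssim(orig, proc),
            rmse=rmse(orig, proc),
        )
        records.append(rec)
        try:
            for side, img in (("original", orig), ("processed", proc)):
                counts = histogram(np.asarray(img))
                if counts.ndim == 1:
                    counts = counts[None, :]
                df = pd.DataFrame(counts.T, columns=[f"ch{c}" for c in range(counts.shape[0])])
                df.insert(0, "intensity", np.arange(256))
                df.to_csv(out.parent / f"{name}_hist_{side}.csv", index=False)
        except OSError as exc:  # pragma: no cover - disk trouble
            logger.warning("histogram side-car for %s failed: %s", name, exc)

    report = pd.DataFrame(
        [{"image": r.image, "mse": r.mse, "psnr_db": r.psnr_db, "ssim": r.ssim, "rmse": r.rmse} for r in records]
    )
    report.to_csv(out, index=False)
    return report
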