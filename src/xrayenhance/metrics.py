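"""No-reference image-quality metrics: AG, H, SF, EI.

Four scalar indicators commonly used to score radiograph enhancement:

* **Average gradient (AG)** — mean magnitude of the forward intensity
  differences, sqrt((f(i,j)−f(i+1,j))² + (f(i,j)−f(i,j+1))²), averaged
  over the (M−1)×(N−1) interior where both forward differences exist.
  A sharpness proxy: a unit-slope ramp scores exactly 1.
* **Information entropy (H)** — Shannon entropy −Σ P(l) log2 P(l) of the
  gray-level histogram, in bits; bounded by log2(number of levels).
* **Spatial frequency (SF)** — quadrature sum sqrt(RF² + CF²) of the
  root-mean-square row and column first differences (each normalized by
  MN, so the ramp gives RF = sqrt((N−1)/N)).
* **Edge intensity (EI)** — mean Sobel gradient magnitude using the
  ¼-scaled 3×3 kernels, with symmetric boundary reflection.  A unit-slope
  ramp gives magnitude 2 at interior pixels ((1+2+1)/4 row weights × the
  2-pixel central difference).

All four are computed on intensities rescaled to the 0..255 gray-level
scale by default (``scale=255``), the convention under which typical
radiograph values are reported (AG of order 1–10, H up to 8 bits);
``scale=None`` uses the image's native dynamic range L−1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .imaging import GrayImage, read_image

__all__ = [
    "MetricsReport",
    "average_gradient",
    "entropy",
    "spatial_frequency",
    "edge_intensity",
    "report",
    "batch_report",
    "SOBEL_GX",
    "SOBEL_GY",
]

# ¼-scaled Sobel templates (horizontal gx, vertical gy)
SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 4.0
SOBEL_GY = np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]) / 4.0


@dataclass(frozen=True)
class MetricsReport:
    """The four quality indicators for one image."""

    image_id: str
    AG: float
    H: float
    SF: float
    EI: float


def _scaled(img: GrayImage, scale: float | None) -> np.ndarray:
    s = (img.L - 1.0) if scale is None else float(scale)
    return img.pixels * s


def average_gradient(img: GrayImage, scale: float | None = 255.0,
                     denominator: str = "interior") -> float:
    """Mean forward-difference gradient magnitude (sharpness proxy).

    ``denominator="interior"`` divides by (M−1)(N−1), the number of pixels
    where both forward differences exist; ``"mn"`` divides by MN (the two
    differ by O(1/M)).
    """
    f = _scaled(img, scale)
    M, N = f.shape
    if M < 2 or N < 2:
        raise ValueError("average gradient needs at least a 2×2 image")
    dr = f[:-1, :-1] - f[1:, :-1]
    dc = f[:-1, :-1] - f[:-1, 1:]
    total = np.sqrt(dr * dr + dc * dc).sum()
    if denominator == "interior":
        return float(total / ((M - 1) * (N - 1)))
    if denominator == "mn":
        return float(total / (M * N))
    raise ValueError("denominator must be 'interior' or 'mn'")


def entropy(img: GrayImage, n_bins: int = 256) -> float:
    """Shannon entropy of the gray-level histogram, in bits (0·log 0 := 0)."""
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    idx = np.clip((img.pixels * n_bins).astype(np.int64), 0, n_bins - 1)
    p = np.bincount(idx.ravel(), minlength=n_bins) / idx.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0)


def spatial_frequency(img: GrayImage, scale: float | None = 255.0) -> float:
    """sqrt(RF² + CF²): RMS of row/column first differences (activity)."""
    f = _scaled(img, scale)
    M, N = f.shape
    if M < 2 or N < 2:
        raise ValueError("spatial frequency needs at least a 2×2 image")
    rf2 = ((f[:, 1:] - f[:, :-1]) ** 2).sum() / (M * N)
    cf2 = ((f[1:, :] - f[:-1, :]) ** 2).sum() / (M * N)
    return float(np.sqrt(rf2 + cf2))


def edge_intensity(img: GrayImage, scale: float | None = 255.0) -> float:
    """Mean Sobel gradient magnitude with ¼-scaled kernels (edge richness)."""
    f = _scaled(img, scale)
    M, N = f.shape
    if M < 3 or N < 3:
        raise ValueError("edge intensity needs at least a 3×3 image")
    gx = convolve(f, SOBEL_GX, mode="reflect")
    gy = convolve(f, SOBEL_GY, mode="reflect")
    return float(np.sqrt(gx * gx + gy * gy).mean())


def report(img: GrayImage, scale: float | None = 255.0, image_id: str | None = None) -> MetricsReport:
    """All four metrics for one image."""
    return MetricsReport(
        image_id=image_id if image_id is not None else img.origin,
        AG=average_gradient(img, scale),
        H=entropy(img),
        SF=spatial_frequency(img, scale),
        EI=edge_intensity(img, scale),
    )


def reports_to_frame(reports: list[MetricsReport], mean_row: bool = True) -> pd.DataFrame:
    """Tabulate reports; optionally append an arithmetic-mean row."""
    df = pd.DataFrame([asdict(r) for r in reports])
    if mean_row and len(df):
        mean = df[["AG", "H", "SF", "EI"]].mean()
        df = pd.concat(
            [df, pd.DataFrame([{"image_id": "mean", **mean.to_dict()}])], ignore_index=True
        )
    return df


def batch_report(directory: str | Path, scale: float | None = 255.0) -> pd.DataFrame:
    """Metric table for every PNG/TIFF in a directory, plus a mean row."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no PNG/TIFF images found in {directory}")
    rows = [report(read_image(p), scale, image_id=p.name) for p in paths]
    return reports_to_frame(rows)
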