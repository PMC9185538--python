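"""Grayscale image container, file I/O and elementary intensity operators.

All processing inside the package happens in floating point on the [0, 1]
intensity scale.  The dynamic range ``L`` of the source file (256 for 8-bit,
65536 for 16-bit) is kept as metadata and consulted only where an operation
is defined on the integer gray-level scale (quality metrics, epsilon
conventions).  Pixel (0, 0) is the top-left corner and arrays are indexed
(row, column) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "read_image",
    "write_image",
    "histogram_equalize",
    "linear_stretch",
]


class FormatError(ValueError):
    """Raised when an input file is not a usable single-channel image."""


@dataclass(frozen=True)
class GrayImage:
    """A single-channel intensity raster.

    Parameters
    ----------
    pixels
        2-D float array with values in [0, 1] (finite).
    L
        Dynamic range of the source data: number of representable gray
        levels, e.g. 256 for 8-bit input.  Retained as metadata.
    origin
        Source-file identifier, or ``"synthetic"`` for generated images.
    """

    pixels: np.ndarray
    L: float = 256.0
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D raster, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if self.L <= 0:
            raise ValueError("dynamic range L must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a copy of this image carrying new pixel data."""
        return replace(self, pixels=pixels)


def read_image(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF, normalized to [0, 1].

    Color images are rejected rather than silently converted: radiographs
    are single-channel and an RGB file usually signals a data problem.
    A trailing singleton channel axis is collapsed.
    """
    path = Path(path)
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 1:
        raw = raw[:, :, 0]
    if raw.ndim != 2:
        raise FormatError(
            f"{path} has shape {raw.shape}; expected a single-channel image "
            "(convert color input to grayscale explicitly before loading)"
        )
    if raw.dtype == np.uint8:
        L = 256.0
    elif raw.dtype == np.uint16:
        L = 65536.0
    else:
        raise FormatError(f"{path}: unsupported dtype {raw.dtype}; expected uint8 or uint16")
    pixels = raw.astype(np.float64) / (L - 1.0)
    return GrayImage(pixels=pixels, L=L, origin=str(path))


def write_image(img: GrayImage, path: str | Path, bits: int = 8) -> None:
    """Write ``img`` as an 8- or 16-bit grayscale PNG or TIFF.

    Values are clipped to [0, 1] and quantized by round-half-to-even
    (``np.rint``) onto 0..2**bits − 1, so a write/read round trip is exact
    to within half a quantization step.
    """
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    vmax = 2**bits - 1
    q = np.rint(np.clip(img.pixels, 0.0, 1.0) * vmax)
    data = q.astype(np.uint8 if bits == 8 else np.uint16)
    iio.imwrite(Path(path), data)


def histogram_equalize(img: GrayImage, n_bins: int = 256) -> GrayImage:
    """Cumulative-distribution remapping of intensities onto [0, 1].

    Each pixel is mapped to the empirical CDF value of its histogram bin,
    which flattens the intensity distribution while preserving rank order
    (the mapping is monotone non-decreasing).  A degenerate histogram with
    a single occupied bin maps to itself unchanged.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    px = img.pixels
    idx = np.clip((px * n_bins).astype(np.int64), 0, n_bins - 1)
    hist = np.bincount(idx.ravel(), minlength=n_bins)
    if np.count_nonzero(hist) <= 1:
        return img.with_pixels(px.copy())
    cdf = np.cumsum(hist) / px.size
    return img.with_pixels(cdf[idx])


def linear_stretch(img: GrayImage) -> GrayImage:
    """Affine map of [min, max] onto [0, 1]; constant images map to zeros."""
    px = img.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))
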