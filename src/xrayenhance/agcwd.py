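"""Adaptive gamma correction with weighting distribution (AGCWD).

AGCWD brightens and re-contrasts an image whose histogram mass sits in the
dark gray levels — the typical radiograph — without the over-enhancement
of a fixed-gamma map.  The histogram pdf is compressed through a weighting
distribution

    pdf_w(v) = pdf_max · ((pdf(v) − pdf_min) / (pdf_max − pdf_min))**α,

its normalized running sum cdf_w drives a per-intensity gamma
γ(v) = 1 − cdf_w(v), and the intensity map is

    T(v) = vmax · (v / vmax)**γ(v).

Since γ(v) ∈ [0, 1] and is non-increasing in v, T is monotone, maps the
endpoints to themselves (T(0) = 0 by the 0**γ := 0 convention,
T(vmax) = vmax) and satisfies T(v) ≥ v on normalized intensities: dense
dark regions are lifted, the bright end is left alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import GrayImage

__all__ = [
    "WeightedHistogram",
    "gamma_correct",
    "weighted_distribution",
    "agcwd_curve",
    "agcwd_lut",
    "agcwd_enhance",
    "agcwd_enhance_raster",
]

DEFAULT_ALPHA = 0.5
_N_LEVELS = 256


@dataclass(frozen=True)
class WeightedHistogram:
    """Histogram statistics backing one AGCWD mapping.

    ``pdf`` is the per-gray-level probability vector, ``pdf_w`` its
    weighted (power-compressed) version, ``cdf_w`` the normalized running
    sum of ``pdf_w`` (non-decreasing, ending at 1), ``alpha`` the
    compression exponent and ``vmax`` the maximum intensity present.
    """

    pdf: np.ndarray
    pdf_w: np.ndarray
    cdf_w: np.ndarray
    alpha: float
    vmax: float


def gamma_correct(img: GrayImage, gamma: float) -> GrayImage:
    """Plain gamma map T(v) = vmax · (v / vmax)**γ with vmax = max(img).

    An all-zero image is returned unchanged (vmax = 0 convention).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    px = img.pixels
    vmax = px.max()
    if vmax <= 0:
        return img.with_pixels(px.copy())
    return img.with_pixels(vmax * (px / vmax) ** gamma)


def weighted_distribution(pdf: np.ndarray, alpha: float) -> np.ndarray:
    """Power-compress a histogram pdf between its min and max (the
    weighting distribution).  A constant pdf is returned unchanged."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pdf = np.asarray(pdf, dtype=np.float64)
    pmin, pmax = pdf.min(), pdf.max()
    if pmax == pmin:
        return pdf.copy()
    return pmax * ((pdf - pmin) / (pmax - pmin)) ** alpha


def agcwd_curve(pdf: np.ndarray, alpha: float) -> WeightedHistogram:
    """Build the weighted histogram and normalized weighted CDF for a pdf
    given on gray levels 0..len(pdf)−1 (vmax = highest occupied level)."""
    pdf = np.asarray(pdf, dtype=np.float64)
    pdf_w = weighted_distribution(pdf, alpha)
    total = pdf_w.sum()
    if total <= 0:
        cdf_w = np.ones_like(pdf_w)
    else:
        cdf_w = np.cumsum(pdf_w) / total
    occupied = np.nonzero(pdf)[0]
    vmax = float(occupied[-1]) if occupied.size else 0.0
    return WeightedHistogram(pdf=pdf, pdf_w=pdf_w, cdf_w=cdf_w, alpha=alpha, vmax=vmax)


def agcwd_lut(wh: WeightedHistogram) -> np.ndarray:
    """Per-level lookup table T(v) = vmax·(v/vmax)**γ(v), γ(v) = 1 − cdf_w(v),
    for gray levels v = 0..len(pdf)−1 (T(0) = 0 by the 0**γ := 0 convention)."""
    n = len(wh.pdf)
    if wh.vmax <= 0:
        return np.arange(n, dtype=np.float64)
    gamma = 1.0 - wh.cdf_w
    v = np.arange(n, dtype=np.float64)
    lut = wh.vmax * np.where(v > 0, (v / wh.vmax) ** gamma, 0.0)
    lut[0] = 0.0
    return lut


def agcwd_enhance_raster(band: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """AGCWD for an arbitrary-range 2-D raster (e.g. an NSST low band).

    The band is min–max stretched to [0, 1] and its histogram taken on 256
    quantized levels; the per-pixel gamma γ = 1 − cdf_w is looked up from
    the pixel's histogram bin but applied to the *continuous* stretched
    intensity, so T(v) ≥ v and monotonicity hold exactly (not merely up to
    quantization).  The inverse affine map restores the band's original
    intensity range.  Constant bands are returned unchanged.
    """
    band = np.asarray(band, dtype=np.float64)
    lo, hi = band.min(), band.max()
    if hi == lo:
        return band.copy()
    unit = (band - lo) / (hi - lo)
    levels = np.clip((unit * _N_LEVELS).astype(np.int64), 0, _N_LEVELS - 1)
    pdf = np.bincount(levels.ravel(), minlength=_N_LEVELS) / levels.size
    wh = agcwd_curve(pdf, alpha)
    gamma = (1.0 - wh.cdf_w)[levels]
    out_unit = np.where(unit > 0, unit**gamma, 0.0)
    return out_unit * (hi - lo) + lo


def agcwd_enhance(img: GrayImage, alpha: float = DEFAULT_ALPHA) -> GrayImage:
    """AGCWD contrast enhancement of a [0, 1] image (see module docstring)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return img.with_pixels(agcwd_enhance_raster(img.pixels, alpha))
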