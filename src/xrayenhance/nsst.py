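"""Nonsubsampled shearlet transform (NSST): forward, inverse, filter banks.

The transform is an undecimated two-stage construction:

1. **Multiscale stage** — an à trous (undecimated) additive pyramid built
   from the separable B3-spline low-pass kernel ``[1, 4, 6, 4, 1]/16``.
   At level ``k`` the kernel is upsampled by ``2**(k-1)`` (zeros inserted)
   and the bandpass band is the difference of successive approximations,
   so the input is exactly the sum of the low band and all bandpass bands.
2. **Directional stage** — each bandpass band is multiplied in the
   frequency domain by ``2**l_k`` smooth angular wedge windows arranged on
   a pseudo-polar partition of the frequency square.  The windows form an
   exact partition of unity (they sum to 1 at every frequency sample), so
   summing a level's directional bands recovers the bandpass band and the
   whole system is a tight frame: synthesis is a plain sum.

All filtering is performed in the frequency domain with periodic
(circular) boundary handling, which makes linearity and circular-shift
covariance exact.  The DFT grid follows the standard ``numpy.fft`` layout
with the zero frequency at index (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
import json

import numpy as np

__all__ = [
    "NsstConfig",
    "SubbandSet",
    "build_shear_filters",
    "pyramid_decompose",
    "pyramid_reconstruct",
    "nsst_forward",
    "nsst_inverse",
    "save_subbands",
    "load_subbands",
]

# B3 spline tap pair used for the à trous pyramid
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class ConfigError(ValueError):
    """Raised for decomposition parameters invalid for the image at hand."""


@dataclass(frozen=True)
class NsstConfig:
    """Decomposition geometry: level count and per-level shearing parameters.

    ``levels`` (the scale parameter j) sets the number of pyramid stages;
    ``shear_params`` holds one shearing parameter l_k per level, each level
    yielding ``2**l_k`` directional sub-bands.
    """

    levels: int = 4
    shear_params: tuple[int, ...] = (2, 2, 2, 2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shear_params", tuple(int(l) for l in self.shear_params))
        if not 1 <= self.levels <= 6:
            raise ConfigError(f"levels must be in 1..6, got {self.levels}")
        if len(self.shear_params) != self.levels:
            raise ConfigError(
                f"shear_params has length {len(self.shear_params)}, expected {self.levels}"
            )
        if any(not 1 <= l <= 5 for l in self.shear_params):
            raise ConfigError(f"each shearing parameter must be in 1..5, got {self.shear_params}")

    @property
    def directions(self) -> tuple[int, ...]:
        """Number of directional sub-bands per level, 2**l_k."""
        return tuple(2**l for l in self.shear_params)


@dataclass
class SubbandSet:
    """One low-frequency band plus per-level directional high-frequency bands.

    Undecimated: every raster has the spatial shape of the source image.
    ``high[k]`` is the list of directional bands of level k+1 (finest first).
    """

    low: np.ndarray
    high: list[list[np.ndarray]]
    config: NsstConfig
    shape: tuple[int, int]

    def validate(self) -> None:
        if self.low.shape != self.shape:
            raise ValueError("low band shape mismatch")
        if len(self.high) != self.config.levels:
            raise ValueError("level count mismatch")
        for k, bands in enumerate(self.high):
            if len(bands) != 2 ** self.config.shear_params[k]:
                raise ValueError(
                    f"level {k + 1} holds {len(bands)} bands, "
                    f"expected {2 ** self.config.shear_params[k]}"
                )
            for b in bands:
                if b.shape != self.shape:
                    raise ValueError(f"band shape {b.shape} != source shape {self.shape}")


def _pseudo_polar_angle(shape: tuple[int, int]) -> np.ndarray:
    """Pseudo-polar orientation coordinate a(u, v) ∈ [0, 4) on the DFT grid.

    Orientations are taken modulo π (a real filter must satisfy
    w(u, v) = w(−u, −v)), which is enforced exactly by canonicalizing the
    sign of each frequency sample before computing the coordinate.  The
    coordinate runs linearly in *slope* along the boundary of the frequency
    square — uniform wedges in ``a`` are the pseudo-polar partition:
    a ∈ [0, 1] on the right cone (slope v/u), (1, 3) on the top cone,
    (3, 4] on the left cone, with a = 0 and a = 4 identified.
    """
    M, N = shape
    fu = np.fft.fftfreq(M)[:, None] * np.ones((1, N))  # vertical frequency
    fv = np.ones((M, 1)) * np.fft.fftfreq(N)[None, :]  # horizontal frequency
    # canonical representative with fu > 0, or fu == 0 and fv >= 0
    flip = (fu < 0) | ((fu == 0) & (fv < 0))
    y = np.where(flip, -fu, fu)
    x = np.where(flip, -fv, fv)
    # Nyquist samples on even grids represent ±1/2 equally, which leaves
    # the sign of the other coordinate ambiguous; resolve both toward the
    # nonnegative representative so the orientation map is exactly even,
    # w(u, v) = w(−u, −v)
    x = np.where(x == -0.5, 0.5, x)
    x = np.where(y == 0.5, np.abs(x), x)
    a = np.zeros(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        right = (x >= y) & (x > 0)
        a[right] = (y / x)[right]
        top = y > np.abs(x)
        a[top] = 2.0 - (x / y)[top]
        left = (x <= -y) & (x < 0)
        a[left] = 4.0 + (y / x)[left]
    a[(x == 0) & (y == 0)] = 0.0  # DC: orientation undefined, assign wedge 0
    return a


@lru_cache(maxsize=32)
def _shear_filter_stack(shape: tuple[int, int], l: int) -> np.ndarray:
    a = _pseudo_polar_angle(shape)
    n_dir = 2**l
    width = 4.0 / n_dir
    stack = np.empty((n_dir, *shape))
    for k in range(n_dir):
        d = np.abs(a - k * width)
        d = np.minimum(d, 4.0 - d)  # periodic distance in orientation
        w = np.where(d < width, np.cos(0.5 * np.pi * d / width) ** 2, 0.0)
        stack[k] = w
    return stack


def build_shear_filters(shape: tuple[int, int], l: int) -> list[np.ndarray]:
    """Frequency-domain directional wedge windows for one level.

    Returns ``2**l`` real nonnegative rasters of the given shape that sum
    to 1 at every frequency sample (exact partition of unity: adjacent
    raised-cosine-squared wedges with 50% overlap).  Window ``k`` is
    centered on pseudo-polar orientation ``k · 4/2**l`` — window 0 on the
    horizontal frequency axis.
    """
    M, N = shape
    if min(M, N) < 8:
        raise ConfigError(f"image shape {shape} too small for directional filtering (need ≥ 8)")
    if not 1 <= l <= 5:
        raise ConfigError(f"shearing parameter must be in 1..5, got {l}")
    return list(_shear_filter_stack((M, N), l))


def _lowpass_response(n: int, step: int) -> np.ndarray:
    """1-D DFT response of the B3 kernel upsampled by ``step`` (à trous)."""
    f = np.fft.fftfreq(n)
    return (6.0 + 8.0 * np.cos(2.0 * np.pi * step * f) + 2.0 * np.cos(4.0 * np.pi * step * f)) / 16.0


def pyramid_decompose(img: np.ndarray, j: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Undecimated additive pyramid: ``img == low + sum(bandpass)`` exactly.

    Level k's bandpass band is the difference between the approximations
    before and after low-pass filtering with the B3 kernel upsampled by
    ``2**(k-1)`` (circular convolution via the FFT).  Returned bandpass
    bands are ordered finest (level 1) to coarsest (level j).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite values in input")
    if j < 1:
        raise ValueError("j must be ≥ 1")
    approx = img
    bandpass: list[np.ndarray] = []
    for level in range(j):
        M, N = approx.shape
        H = np.outer(_lowpass_response(M, 2**level), _lowpass_response(N, 2**level))
        smoother = np.fft.ifft2(np.fft.fft2(approx) * H).real
        bandpass.append(approx - smoother)
        approx = smoother
    return approx, bandpass


def pyramid_reconstruct(low: np.ndarray, bandpass: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`pyramid_decompose` — a plain sum by construction."""
    out = low.copy()
    for b in bandpass:
        out = out + b
    return out


def nsst_forward(img, config: NsstConfig | None = None) -> SubbandSet:
    """Decompose an image into one low band and per-level directional bands.

    Accepts a :class:`~xrayenhance.imaging.GrayImage` or a bare 2-D array.
    """
    pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if config is None:
        config = NsstConfig()
    M, N = pixels.shape
    if min(M, N) < 8:
        raise ConfigError(f"image shape {(M, N)} too small for NSST")
    low, bandpass = pyramid_decompose(pixels, config.levels)
    high: list[list[np.ndarray]] = []
    for k, band in enumerate(bandpass):
        windows = _shear_filter_stack((M, N), config.shear_params[k])
        F = np.fft.fft2(band)
        high.append([np.fft.ifft2(F * w).real for w in windows])
    return SubbandSet(low=low, high=high, config=config, shape=(M, N))


def nsst_inverse(bands: SubbandSet) -> np.ndarray:
    """Reconstruct the image from a subband set.

    Because the directional windows partition unity and the pyramid is
    additive, synthesis is a sum: directional bands recombine into each
    level's bandpass band, and low + bandpass bands give the image.
    Perfect reconstruction holds to floating-point accuracy.
    """
    bands.validate()
    out = bands.low.copy()
    for level_bands in bands.high:
        for b in level_bands:
            out += b
    return out


def save_subbands(bands: SubbandSet, directory: str | Path) -> None:
    """Dump a subband set to a directory of TIFF rasters plus a manifest.

    Debugging/inspection aid; the enhancement path never round-trips
    through disk.  Rasters are written as 32-bit float TIFFs.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "low.tif", bands.low.astype(np.float32))
    for k, level_bands in enumerate(bands.high):
        for d, b in enumerate(level_bands):
            tifffile.imwrite(directory / f"high_L{k + 1}_D{d:02d}.tif", b.astype(np.float32))
    manifest = {
        "levels": bands.config.levels,
        "shear_params": list(bands.config.shear_params),
        "shape": list(bands.shape),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_subbands(directory: str | Path) -> SubbandSet:
    """Read back a subband set written by :func:`save_subbands`."""
    import tifffile

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = NsstConfig(levels=manifest["levels"], shear_params=tuple(manifest["shear_params"]))
    low = tifffile.imread(directory / "low.tif").astype(np.float64)
    high = []
    for k in range(config.levels):
        high.append(
            [
                tifffile.imread(directory / f"high_L{k + 1}_D{d:02d}.tif").astype(np.float64)
                for d in range(2 ** config.shear_params[k])
            ]
        )
    return SubbandSet(low=low, high=high, config=config, shape=tuple(manifest["shape"]))
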