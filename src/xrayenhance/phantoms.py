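"""Synthetic X-ray-like phantoms for tests, examples and benchmarks.

Real radiographs have low global contrast, a histogram whose mass sits in
the dark gray levels, fine anatomical/structural edges, and noise.  The
generator composes analytic primitives (disks, rods, step wedges,
sinusoidal texture patches) over a dark background, then applies Gaussian
blur and additive Gaussian noise.  Everything is deterministic given the
spec's seed, and with blur and noise disabled the pixel values are
piecewise analytic and exactly recomputable.

Overlapping structures composite last-wins: each primitive assigns its
value over its footprint, overwriting whatever was rendered before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import GrayImage

__all__ = [
    "Disk",
    "Rod",
    "StepWedge",
    "TexturePatch",
    "PhantomSpec",
    "generate",
    "chest_phantom_spec",
    "standard_suite",
]


@dataclass(frozen=True)
class Disk:
    """Filled circle at (row, col) center with radius r; value = background + contrast."""

    center: tuple[float, float]
    radius: float
    contrast: float

    def render(self, canvas: np.ndarray, background: float) -> None:
        rr, cc = np.ogrid[: canvas.shape[0], : canvas.shape[1]]
        mask = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2
        canvas[mask] = background + self.contrast


@dataclass(frozen=True)
class Rod:
    """Thick line segment (capsule) between two (row, col) endpoints."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float
    contrast: float

    def render(self, canvas: np.ndarray, background: float) -> None:
        rr, cc = np.mgrid[: canvas.shape[0], : canvas.shape[1]].astype(np.float64)
        p0 = np.array(self.start)
        d = np.array(self.end) - p0
        L2 = float(d @ d)
        if L2 == 0:
            t = np.zeros_like(rr)
        else:
            t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2, 0.0, 1.0)
        dist2 = (rr - p0[0] - t * d[0]) ** 2 + (cc - p0[1] - t * d[1]) ** 2
        canvas[dist2 <= (self.width / 2.0) ** 2] = background + self.contrast


@dataclass(frozen=True)
class StepWedge:
    """Axis-aligned rectangle of n_steps vertical bands of rising intensity."""

    top_left: tuple[int, int]
    shape: tuple[int, int]
    n_steps: int
    contrast: float

    def render(self, canvas: np.ndarray, background: float) -> None:
        r0, c0 = self.top_left
        h, w = self.shape
        for s in range(self.n_steps):
            lo = c0 + (s * w) // self.n_steps
            hi = c0 + ((s + 1) * w) // self.n_steps
            level = background + self.contrast * (s + 1) / self.n_steps
            canvas[r0 : r0 + h, lo:hi] = level


@dataclass(frozen=True)
class TexturePatch:
    """Rectangle carrying a product-of-sines texture of a given period."""

    top_left: tuple[int, int]
    shape: tuple[int, int]
    period: float
    amplitude: float
    offset: float = 0.0

    def render(self, canvas: np.ndarray, background: float) -> None:
        r0, c0 = self.top_left
        h, w = self.shape
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        tex = self.amplitude * np.sin(2 * np.pi * rr / self.period + self.offset) * np.sin(
            2 * np.pi * cc / self.period + self.offset
        )
        canvas[r0 : r0 + h, c0 : c0 + w] = background + self.amplitude + tex


Primitive = Disk | Rod | StepWedge | TexturePatch


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic description of a synthetic radiograph.

    ``illumination`` adds a smooth centered Gaussian falloff (scale 0.6 of
    the short side) after the structures are rendered, emulating the
    beam/scatter field of a real exposure; it also guarantees the image
    has no perfectly constant region, which a real detector never shows.
    """

    shape: tuple[int, int] = (440, 440)
    background_level: float = 0.05
    structures: tuple[Primitive, ...] = ()
    illumination: float = 0.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0


def generate(spec: PhantomSpec) -> GrayImage:
    """Render a phantom: primitives (last wins), illumination falloff,
    blur, seeded noise, clip to [0, 1]."""
    canvas = np.full(spec.shape, spec.background_level, dtype=np.float64)
    for s in spec.structures:
        s.render(canvas, spec.background_level)
    if spec.illumination > 0:
        M, N = spec.shape
        rr, cc = np.mgrid[0:M, 0:N].astype(np.float64)
        r2 = ((rr - 0.5 * M) ** 2 + (cc - 0.5 * N) ** 2) / (0.6 * min(M, N)) ** 2
        canvas = canvas + spec.illumination * np.exp(-r2)
    if spec.blur_sigma > 0:
        canvas = gaussian_filter(canvas, spec.blur_sigma, mode="reflect")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return GrayImage(pixels=np.clip(canvas, 0.0, 1.0), L=256.0, origin="synthetic")


def chest_phantom_spec(shape: tuple[int, int] = (440, 440), seed: int = 0) -> PhantomSpec:
    """A low-contrast chest-radiograph-like phantom.

    Dark background with two faint lung-field disks, a brighter spine rod,
    rib-like thin rods, a step wedge and a fine texture patch; mild blur
    and noise.  Most of the histogram mass stays in the lowest intensity
    quartile, the regime contrast enhancement is meant for.
    """
    M, N = shape
    ribs = tuple(
        Rod(
            start=(0.18 * M + 0.12 * M * k, 0.12 * N),
            end=(0.24 * M + 0.12 * M * k, 0.88 * N),
            width=0.012 * min(M, N),
            contrast=0.16,
        )
        for k in range(5)
    )
    structures: tuple[Primitive, ...] = (
        Disk(center=(0.45 * M, 0.30 * N), radius=0.20 * min(M, N), contrast=0.08),
        Disk(center=(0.45 * M, 0.70 * N), radius=0.20 * min(M, N), contrast=0.08),
        *ribs,
        Rod(
            start=(0.08 * M, 0.50 * N),
            end=(0.92 * M, 0.50 * N),
            width=0.05 * min(M, N),
            contrast=0.13,
        ),
        StepWedge(
            top_left=(int(0.86 * M), int(0.08 * N)),
            shape=(int(0.08 * M), int(0.40 * N)),
            n_steps=8,
            contrast=0.18,
        ),
        TexturePatch(
            top_left=(int(0.10 * M), int(0.62 * N)),
            shape=(int(0.14 * M), int(0.24 * N)),
            period=6.0,
            amplitude=0.05,
        ),
    )
    return PhantomSpec(
        shape=shape,
        background_level=0.05,
        structures=structures,
        illumination=0.10,
        noise_sigma=0.004,
        blur_sigma=1.5,
        seed=seed,
    )


def _multiscale_texture(shape: tuple[int, int] = (256, 256), seed: int = 11) -> GrayImage:
    """Radiograph-like multiscale texture fixture for scale-sweep studies.

    A smooth illumination falloff spans the dynamic range (no constant
    region, dark-dominant histogram); sinusoids at periods 4, 8, 16 and
    32 px put a small equal amplitude at every dyadic scale a level sweep
    probes.  Amplitudes are kept at the fraction-of-range level fine
    detail has in real radiographs, so enhancement does not saturate.
    """
    M, N = shape
    rr, cc = np.mgrid[0:M, 0:N].astype(np.float64)
    r2 = ((rr - 0.5 * M) ** 2 + (cc - 0.5 * N) ** 2) / (0.6 * min(M, N)) ** 2
    canvas = 0.05 + 0.22 * np.exp(-r2)
    for i, period in enumerate((4.0, 8.0, 16.0, 32.0)):
        phase = 0.7 * i
        canvas += 0.001 * np.sin(2 * np.pi * rr / period + phase) * np.sin(
            2 * np.pi * cc / period + phase
        )
    rng = np.random.default_rng(seed)
    canvas += rng.normal(0.0, 0.00025, size=shape)
    return GrayImage(np.clip(canvas, 0.0, 1.0), L=256.0, origin="synthetic")


def standard_suite() -> dict[str, GrayImage]:
    """The fixed, seeded fixture set used across tests and examples.

    Keys: ``flat``, ``ramp`` (unit gray-level steps on the 0..255 scale),
    ``step_edge``, ``step_edge_noise``, ``texture`` (multiscale),
    ``chest_phantom`` (440×440 low-contrast), ``oracle32`` (small smooth
    random image for brute-force comparisons).
    """
    suite: dict[str, GrayImage] = {}
    suite["flat"] = GrayImage(np.full((64, 64), 0.5), L=256.0)

    col = np.arange(64, dtype=np.float64)
    suite["ramp"] = GrayImage(np.tile(col / 255.0, (64, 1)), L=256.0)

    step = np.full((64, 64), 0.2)
    step[:, 32:] = 0.7
    suite["step_edge"] = GrayImage(step, L=256.0)

    rng = np.random.default_rng(7)
    noisy = np.clip(step + rng.normal(0.0, 0.05, size=step.shape), 0.0, 1.0)
    suite["step_edge_noise"] = GrayImage(noisy, L=256.0)

    suite["texture"] = _multiscale_texture()
    suite["chest_phantom"] = generate(chest_phantom_spec())

    rng = np.random.default_rng(32)
    small = gaussian_filter(rng.random((32, 32)), 1.0, mode="reflect")
    suite["oracle32"] = GrayImage(np.clip(small, 0.0, 1.0), L=256.0)
    return suite
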