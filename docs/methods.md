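# Methods

This note documents the models and numerical choices behind
`xrayenhance`: what each stage computes, which parameters matter and
why the defaults are what they are, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Intensity conventions

All processing happens in float64 on the [0, 1] intensity scale. The
source dynamic range `L` (256 for 8-bit, 65536 for 16-bit files) is kept
as `GrayImage` metadata and used in two places only: quantization on
write, and the metric reporting scale. Quality metrics are computed on
intensities rescaled to 0..255 regardless of source depth, the
convention under which radiograph metric values are customarily quoted
(AG of order 1–10, H up to 8 bits); `scale=None` switches to the native
`L−1` scale. Pixel (0, 0) is top-left; arrays are (row, column).

Color input is rejected, not silently converted: radiographs are
single-channel, and an RGB file usually signals an upstream data
problem.

## Nonsubsampled shearlet transform

**Multiscale stage.** An à trous (undecimated) pyramid built from the
separable B3-spline kernel `[1,4,6,4,1]/16`, upsampled by `2^(k−1)` at
level `k`, applied as frequency-domain multiplication with periodic
boundary handling. The bandpass band is the *difference* of successive
approximations, so the decomposition is additive: the input equals the
low band plus all bandpass bands identically, and pyramid
reconstruction is a plain sum. This makes perfect reconstruction a
structural property rather than a numerical target.

**Directional stage.** Each bandpass band is multiplied in the DFT
domain by `2^l` real nonnegative wedge windows. The orientation
coordinate is pseudo-polar (linear in slope along the boundary of the
frequency square, periodic with the orientation taken modulo π), and
the windows are raised-cosine-squared bumps with 50% overlap, so
adjacent pairs satisfy cos² + sin² = 1 and the bank partitions unity
*exactly* at every frequency sample. Consequences, all tested:

- directional bands at a level sum exactly to that level's bandpass
  band; synthesis is again a plain sum and the full transform satisfies
  `‖inverse(forward(x)) − x‖∞ ≈ 1e−15`;
- the transform is linear and covariant under circular shifts (no
  decimation anywhere), which is what suppresses pseudo-Gibbs ringing;
- window `k` equals 1 on its central orientation ray.

Orientation is canonicalized so `w(u,v) = w(−u,−v)` holds exactly,
including at the Nyquist row/column of even-sized grids, where the ±1/2
frequency representative is resolved toward the nonnegative side; the
filters therefore have real impulse responses. The DC sample is
assigned to wedge 0 (any assignment works — the partition of unity is
what reconstruction relies on, and the pyramid routes DC to the low
band anyway).

Degenerate/edge cases: images smaller than 8×8 are rejected; levels
j ∈ 1..6 and shearing parameters l ∈ 1..5 are enforced at construction.

## AGCWD (low band)

Parameters: `alpha` (histogram-compression exponent, default 0.5 —
a moderate midpoint of the usable range; the behavior of the pipeline
is not sensitive to it and it is exposed on the CLI).

The band is min–max stretched to [0, 1], its histogram taken on 256
levels, the weighting distribution and normalized weighted CDF formed,
and the per-intensity gamma `γ(v) = 1 − cdf_w(v)` applied. Two
numerical choices:

- the gamma is looked up from the pixel's histogram bin but applied to
  the *continuous* stretched intensity, so monotonicity and the
  brightening bound `T(v) ≥ v` hold exactly rather than to within a
  quantization step;
- `T(0) = 0` by the convention `0^γ := 0` (including γ = 0), keeping
  the dark endpoint fixed; the bright endpoint is fixed because the
  stretched maximum maps through base 1.

The stretch-then-restore convention exists because pyramid low bands
are not guaranteed to occupy [0, 1]; the inverse affine map returns the
enhanced band to its original range. Constant bands (and constant
histograms in the weighting step) pass through unchanged.

## Gradient-domain guided filtering (high bands)

Parameters, with defaults from the operating point: window radius
`ς = 16` pixels, regularization `λ = 0.5` (on normalized intensities —
the scale convention is documented here because λ trades off against
the squared intensity scale), detail gain `ξ = 5`, stabilizer
`ε = 1e−6` (the (0.001·L)² convention evaluated at L = 1).

Each sub-band is filtered self-guided (G = X): a per-window linear
regression with closed form

    a = (μ_{GX} − μ_G μ_X + λ Γ γ) / (σ²_G + λ Γ),   b = μ_X − a μ_G,

output `Z = ā G + b̄` with ā, b̄ window means of the coefficients. The
edge-aware weight is `Γ(p') = mean_p (χ(p')+ε)/(χ(p)+ε)` with χ the
product of the 3×3 and (2ς+1)×(2ς+1) local standard deviations, and the
edge factor is the sigmoid `γ = expit(η(χ − μ_χ))`, `η = 4/(μ_χ −
min χ)` — near 1 on edges (slope pinned to 1: no halo), near 0 in
smooth regions (full smoothing). The regularizer *multiplies* Γ in this
closed form; the alternative convention that divides λ by Γ is available
as `weight_mode="divide"` — the two differ only in the effective
per-pixel λ.

Numerical choices: window statistics use `uniform_filter` with
symmetric reflection (O(MN), no dark-frame artifacts); sub-bands are
signed and no offset is applied; a constant guide yields χ ≡ 0, Γ ≡ 1
and γ ≡ 0 (the smooth-region limit) without computing η; for images
with a side under 64 the radius is clamped to min(M,N)/4 with a logged
warning. Note that the mean of Γ over the image is ≥ 1 (it equals
`mean(χ+ε)·mean(1/(χ+ε))`, an AM–HM product), not 1; only positivity
and the constant-guide limit are structural.

Detail boosting `Z + ξ(X − Z)` is exactly affine in ξ; at ξ = 1 the
band is returned unchanged (exact identity, short-circuited).

## Pipeline

Stage order: equalize → forward NSST → AGCWD(low) →
GDGF+boost(each high band) → inverse NSST → clip to [0, 1]. The
reconstruction is **clipped**, not rescaled: detail boosting
deliberately overshoots, and a global rescale would undo the contrast
gained on the low band. The clipped-pixel fraction is logged at debug
level. The pipeline contains no randomness; outputs are byte-identical
across runs.

Defaults (`EnhanceConfig()`): j = 4 levels, shearing parameters
(2,2,2,2), ς = 16, λ = 0.5, ξ = 5, α = 0.5, equalization on.

**Interaction between boosting and clipping.** On images whose
equalized histogram puts mass near both ends of the range — which plain
global equalization always produces — boosted bands overshoot and the
clip saturates several percent of pixels. Saturated areas lose fine
gradient, so each additional boosted level trades its gradient gain
against extra flattening. In level sweeps on the synthetic texture
fixture the unclipped reconstruction's AG rises monotonically with
depth with diminishing increments, while the clipped output's AG peaks
at three levels and dips below a percent at four; EI behaves the same
way. The saturation trade-off is a real property of
equalize-then-boost enhancement at these amplitudes, and sweep results
on synthetic fixtures should be read with it in mind.

## Quality metrics

All four operate on the 0..255 scale (see conventions) and are zero on
constant images.

- **AG**: mean of `sqrt((f(i,j)−f(i+1,j))² + (f(i,j)−f(i,j+1))²)` over
  the (M−1)×(N−1) interior where both forward differences exist; a
  `denominator="mn"` option divides by MN instead (the two differ by
  O(1/M), and the convention behind published tables is generally not
  recoverable). A unit-step column ramp scores exactly 1.
- **H**: Shannon entropy `−Σ P log₂ P` of the 256-bin histogram, bits;
  bounded by 8.
- **SF**: `sqrt(RF² + CF²)`, RF/CF the row/column first-difference
  energies normalized by MN, so the ramp gives `RF = sqrt((N−1)/N)`.
- **EI**: mean Sobel gradient magnitude with ¼-scaled 3×3 kernels and
  symmetric reflection. The ¼-scaled kernels respond to a unit-step
  ramp with magnitude 2 in the interior ((1+2+1)/4 row weights times
  the two-pixel central difference), hence a full-image mean of
  2 − 2/N under reflection; an "EI = 1 on the ramp" expectation would
  correspond to ⅛-scaled kernels, which these are not.

All three gradient-type metrics are exactly invariant under intensity
offsets and scale linearly with intensity scaling; H is
binning-invariant under offsets that do not cross bin edges.

## Synthetic fixtures

The `phantoms` module renders deterministic X-ray-like images from
analytic primitives (disks, capsule rods, step wedges, sinusoidal
texture patches) composited last-wins over a dark background, plus an
optional smooth Gaussian illumination falloff, Gaussian blur and seeded
additive Gaussian noise. Design choices:

- **Dark-dominant histograms**: the default chest-like phantom keeps
  >60% (in practice ~92%) of its mass in the lowest intensity quartile,
  the regime this kind of enhancement targets.
- **No perfectly constant regions**: the illumination falloff
  guarantees a nonzero gradient everywhere. A real detector never
  records an exactly constant field, and exact histogram equalization
  maps a flat-region histogram spike across its full quantile share of
  the output range, exploding background noise regardless of its σ —
  an artifact of the fixture, not of radiographs.
- **Radiograph-scale amplitudes**: the multiscale texture fixture
  (256×256; equal-amplitude sinusoids at periods 4, 8, 16, 32 px,
  amplitude 1e−3; noise σ = 2.5e−4) keeps fine detail at the small
  fraction of dynamic range it has in real radiographs, so that
  enhanced-output metric magnitudes land in the customary AG ≈ 1–10
  band and the pipeline is not driven into wholesale saturation.
- Additive Gaussian noise is the minimal model that exercises the
  denoising path; it does not emulate Poisson photon statistics,
  scatter, detector MTF or anatomy. Passing tests on these fixtures
  demonstrate the stated mathematical contracts and qualitative
  behaviors, not clinical image quality.

Noise- and blur-free specs are piecewise analytic and exactly
recomputable; everything is deterministic given the spec seed.

## Known limitations

- Global histogram equalization in stage 1 amplifies noise in dense
  histogram regions; the GDGF stage reduces but does not remove this.
- ξ = 5 boosting guarantees overshoot; the clip keeps outputs valid but
  saturates a logged fraction of pixels (see the pipeline section).
- The shear filter bank partitions unity but is not orthonormal;
  per-band energies overlap between adjacent wedges.
- No DICOM support: windowing/rescale semantics are out of scope;
  convert to PNG/TIFF first. No color, no video, no decimated or
  compactly-supported shearlet variants.
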