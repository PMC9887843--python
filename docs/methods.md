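# Methods

This note documents the models implemented in `ndvicam`, the default
parameter values and why they were chosen, what the synthetic data
emulates, and the numerical conventions used throughout.

## Radiometric model and encoding

Reflectance images hold relative reflectance in percent (0–100). NDVI is
`(NIR − RED)/(NIR + RED)` on percent reflectance; pixels with total signal
`NIR + RED ≤ 1e−6 %` are undefined and masked rather than given a value.

Products are stored as 16-bit grayscale PNG with a linear code scale:
reflectance 0–100 % and NDVI −1…+1 both map onto 0–65 536. The nominal top
of scale does not fit in 16 bits, so stored codes clamp at 65 535 while the
decode formula `NDVI = code·(2/65536) − 1` keeps the exact denominator;
the worst-case round-trip error is one code (2/65536 in NDVI, ≈3·10⁻⁵).
Rounding is half-away-from-zero, chosen because it is deterministic and
platform independent (banker's rounding would make codes depend on parity).
Out-of-range values saturate; they are additionally flagged in the validity
mask, which is carried through every stage and stored as a sidecar PNG.

## Calibration

The empirical-line model is fitted in the direction it is applied:

```
R/100 = a · (DN/255)^γ + b
```

* **Six-reference mode** (default): `a`, `b`, `γ` by nonlinear least
  squares; γ bounded to [1, 4] and started at 2.2 (near the sRGB-like
  exponents consumer cameras apply). Requires ≥ 4 distinct DNs.
* **Two-reference mode**: brightest and darkest materials only; γ is held
  fixed (default 2.12766, an empirically determined de-gamma exponent for
  this camera family, user-overridable) and `a`, `b` solve the 2×2 system
  exactly.

Patch statistics use the mean DN of each reference ROI after eroding a 10 %
margin from every edge (so ROI placement need not be pixel-perfect; patches
under 10 px/side get no erosion) and excluding pixels at DN ≥ 250 as
saturated. A patch mean ≥ 240 warns; a patch with > 50 % excluded pixels is
an error. Exposure selection returns the longest shutter in a series whose
brightest patch mean stays below DN 240.

With six noiseless reference points the fit recovers γ to 10⁻³. Rounding
DNs to 8-bit integers leaves a genuine identifiability floor: across random
(a, b, γ) truths roughly 95 % of fits land within 0.05 of the true γ and
the remainder slightly beyond — this is quantization noise, not a fit
defect, and the test suite asserts the bound at the 95th percentile.

## Red-leak correction

The NIR camera's filter transmits a small fraction of red light. The leak
fraction is predicted from spectral curves sampled on a common 1 nm grid
(400–900 nm) as

```
f = S_red / (S_red + S_nir),   S_band = Σ_λ∈band I(λ)·R(λ)·T(λ)
```

with bands taken as centre ± fwhm/2. Correction is per pixel:
`NIR_corr = NIR_meas − f·RED`, clamped at 0 with clamped pixels flagged.

Two deliberate design choices here:

* **Correction operates in reflectance space, after calibration.** Working
  on calibrated reflectance keeps the subtraction linear and independent of
  camera gamma, at the cost of assuming the leak survives calibration as an
  additive reflectance offset.
* **The NIR calibration targets the contaminated panel reflectances.** The
  NIR camera images the reference patches through the same leaky filter, so
  the signal it records for a patch is `R_nir + f·R_red` — both known. When
  a leak fraction is available, the pipeline fits the NIR model against
  these adjusted targets; the calibrated image then estimates the
  *measured* (contaminated) reflectance, and the per-pixel subtraction
  removes the leak exactly once. Fitting against the uncontaminated NIR
  reflectances instead makes the fit absorb most of the leak and the
  explicit subtraction double-counts it (≈0.04 NDVI bias at f = 0.1).

## Registration

The two cameras sit on a rigid mount, so the default registration model is
a pure translation. The estimator is exhaustive normalized
cross-correlation over integer shifts within a search radius (correlation
computed on the valid overlap only), refined to sub-pixel accuracy with 1-D
parabolic fits along each axis of the correlation surface. On smooth
textured scenes it recovers shifts up to ±20 px with error well under
0.5 px, including at 20 dB signal-to-noise. Resampling is bilinear; pixels
whose source falls outside the frame, or that interpolate from any masked
pixel, are masked. Feature-based affine registration is an extension point,
not part of the core model.

## Region statistics

Per-region NDVI summaries use the population standard deviation (the region
is the whole population of interest, not a sample), `cov = sd/mean`
(undefined when |mean| < 10⁻¹²) and Fisher–Pearson skewness
`g1 = m3/m2^{3/2}`, defined as 0 for zero-variance regions. Sums over
constant regions accumulate ~10⁻¹⁶ rounding residue; standard deviations
below 10⁻¹² of the data scale are snapped to zero so constant regions
report exact zeros.

## Synthetic scenes

The simulator exists so every pipeline stage can be exercised against known
ground truth.

* **Leaf model.** A simplified stand-in for a radiative-transfer leaf
  model, keeping only the properties the pipeline depends on: for
  λ ≤ 700 nm, `R = 2 + 48·exp(−k(λ)·cab)` with the absorption kernel
  `k(λ) = 0.08·exp(−((λ−680)/45)²)` peaking at the 680 nm chlorophyll
  absorption maximum; for λ ≥ 720 nm a pigment-independent 47 % NIR
  plateau; linear blend between. The constants (2 % floor, 48 % amplitude,
  47 % plateau, k₀ = 0.08 cm²/µg, 45 nm width) are fixture choices giving
  realistic magnitudes. The model yields NDVI strictly increasing in
  chlorophyll over 0–60 µg cm⁻², stronger red sensitivity away from
  680 nm, and an exactly flat NIR response beyond 720 nm. Real leaves have
  structured NIR spectra, water absorption features and specular effects
  that this model deliberately omits — tests passing on it demonstrate
  pipeline correctness, not leaf-model realism.
* **Camera model.** `DN = clamp₀²⁵⁵(round(255·(g·R/100)^{1/γ} + ε))` with
  additive Gaussian DN noise ε (default sd 1.5 DN) applied after gamma and
  before rounding; photon noise is not modelled. The gain g is proportional
  to shutter speed and illumination, normalized so the factory shutter
  settings (400 µs red / 2500 µs NIR at 800 µmol m⁻² s⁻¹) run at gain 0.8 —
  the headroom the exposure rule (brightest reference < DN 240) enforces in
  real operation. The NIR frame sees `R_nir + f·R_red` and is translated by
  the inter-camera shift (bilinear, edge-padded) before encoding. Rendering
  is byte-deterministic given the scene seed.
* **Spectrometer.** Ideal 1 nm-resolution curves referenced to a 99 %
  diffuse standard (the standard itself reads 99 %); leaf targets return
  the leaf model's curve exactly, with no instrument noise.

Default scene conditions: leak fraction 0.10 (middle of the filter's 5–15 %
red transmission), inter-camera shift (2.0, −1.5) px, gamma 2.12766, noise
sd 1.5 DN, illumination 800 µmol m⁻² s⁻¹, 24 × 24 px patches.

## Verification sweep

For candidate wavelengths λ the sweep computes spectrometer NDVI per sample
at (λ, NIR_fixed) or (RED_fixed, λ) and summarizes disagreement as the mean
absolute relative difference in percent, with the spectrometer value as
denominator (the direction a "percent difference from the reference
instrument" implies). Samples with spectrometer NDVI exactly 0 are excluded
at that wavelength with a warning. The best wavelength is the argmin, ties
broken toward the shorter wavelength; the default step is 10 nm with 1 nm
available. On simulated data the red sweep (600–700 nm, NIR fixed at
750 nm) recovers 620 nm. Because the simulated NIR plateau is exactly flat
from 720 nm, the NIR sweep (700–800 nm) ties across 720–800 nm and the
tie-break reports 720 nm — the scientifically meaningful statement is that
the NIR band choice anywhere on the plateau does not alter NDVI.

## Pipeline and I/O conventions

Pixel coordinates are 0-based (row, col) with half-open ROIs and top-left
origin. Every 16-bit output carries a JSON sidecar (payload, scale, band)
and a mask PNG when any pixel is masked; a 16-bit image without its sidecar
is refused, as are lossy input formats. The stage order is: panel
extraction (both cameras) → leak model → calibration fits → reflectance
conversion → leak subtraction → registration → NDVI → encoding → region
statistics; each stage logs its parameters and a failure aborts with the
stage name. Outputs are byte-reproducible from (config, seed). A fitted
calibration can be saved as JSON and reused across images taken under the
same lighting.

## Problem sizes

Tests and the acceptance script use 24 × 24 px patches, scenes of roughly
100×100–300×100 px, 24 simulated leaves for the sweep, 100 random draws for
calibration recovery and 50 seeded shifts for registration recovery — sizes
chosen to exercise every code path with comfortable statistical margins.

## Known limitations

* Vignetting, lens distortion and BRDF/angular effects are not modelled or
  corrected.
* Registration is translation-only; parallax at close range needs the
  affine extension.
* Green/blue crosstalk onto the red Bayer channel is folded into the scalar
  band reflectance, not simulated or corrected separately.
* The leaf model is not a substitute for radiative-transfer simulation;
  quantitative chlorophyll–reflectance relationships from it should not be
  interpreted biologically.
* Real-plant agreement statistics depend on real imagery and are outside
  what the synthetic suite can establish.
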