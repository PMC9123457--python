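# Methods

## The measurement model

A dual-beam spectrophotometer photograph contains two near-vertical
diffraction stripes over a dark field: the reference beam (left) and the
sample beam (right), both dispersed so that pixel row maps monotonically to
wavelength with the red end at the top. For transmitted intensities
I (sample) and I₀ (reference) at a wavelength, the Beer–Lambert law gives
the absorbance A = −ln(I/I₀) = ε c l, linear in concentration c with path
length l and molar attenuation ε(λ).

Two instrument effects sit between that ideal and the pixels:

1. **Beam asymmetry.** The left and right optical paths are not perfectly
   matched, but their intensity *ratio* is constant over a session. A blank
   frame (two empty cuvettes) measures that ratio once; in absorbance
   space it is an additive offset `A_blank`, subtracted from every
   subsequent raw absorbance.
2. **Sensor nonlinearity.** Stored pixel values follow a power law
   P ∝ Iⁿ with n < 1 for typical phone camera processing. Logarithms turn
   this into a multiplicative compression: every measured absorbance, and
   hence every calibration slope, is n times its true value (slope n·ε·l
   instead of ε·l). `correct_exponent` divides the compression out;
   `estimate_exponent` fits n as the log-log slope of pixel value against
   known relative intensity.

Natural logarithms are the canonical convention throughout; `to_decadic`
converts to the base-10 absorbance commercial instruments report
(A₁₀ = A/ln 10).

## Pipeline stages and numerical choices

**Normalization.** All images become float64 in [0,1] (8-bit ÷ 255,
16-bit ÷ 65535); alpha is dropped, grayscale rejected, frames below 64×64
rejected as too small for few-nm peak localization.

**Orientation.** The red-dominant end of the stripes must be at row 0.
High-vibrancy pixels (≥20% of the map maximum) are split into top and
bottom halves; whichever half has the larger mean R−B excess (at least
0.02) is the red end. A frame with no chromatic signal — e.g. uniform white
stripes — cannot be oriented and errors out rather than guessing.

**Localization.** Vibrancy is |R−G|+|R−B|+|G−B| = 2·(max−min); it is
permutation-invariant, positively homogeneous, and exactly zero on grays,
so a uniform gray background offset cannot move a stripe boundary. The map
is collapsed by *summation* along each axis (an explicit design choice;
thresholding the summed profile weights wide dim stripes and narrow bright
ones comparably) and thresholded at 20% of the profile peak. Gaps of ≤2
pixels between above-threshold runs are bridged before counting stripes so
single-pixel noise dropouts cannot split a stripe; the worked thresholding
primitive itself (`threshold_intervals`) performs no bridging. Fewer or
more than two column intervals raise distinct errors (higher-order
diffraction images are the usual cause of "more"). Row extent is computed
per stripe so a sample spectrum with missing portions cannot truncate the
reference. As a misalignment guard, each stripe's vibrancy-weighted column
centroid is regressed on row index; an estimated tilt above 2.5°
(configurable) raises an error. Localization is verified to IoU ≥ 0.7
against ground truth up to 2° of true rotation; beyond roughly 3.5° the
tilt guard fires.

**Wavelength calibration.** Per-channel row means across each stripe give
an intensity profile. The reference profile's red- and blue-channel argmax
rows (after a 5-row moving average; raw argmax is noise-fragile) anchor an
affine row→nm map. Affinity is exact for first-order grating dispersion at
small angles and is documented as an approximation otherwise; exactly two
anchors determine it. Argmax ties break toward the smaller row index — with
smoothing enabled, a symmetric plateau therefore resolves to its smoothed
center, and the raw tie rule is observable at `smooth_halfwidth=0`. The
anchor wavelengths are configuration, not constants: they are properties
of the LED, measured once per device type; the defaults (600/452 nm) are
plausible white-LED values and must be overridden for real hardware. The
"average curve" is kept per-channel (peaks are named per channel) rather
than averaged across channels.

**Photometry.** Band intensity is the *mean* (not sum — so the half-width
does not rescale intensities) of a channel over the rows within ±5 nm
(default) of the target wavelength. The default channel policy selects the
channel with the largest band mean in the *reference* profile — chosen on
the reference so the selection cannot depend on analyte concentration — and
applies it to both beams; a summed-RGB policy is available. Any band value
at ≥0.995 triggers a saturation warning, since ratios are meaningless at
clipping. Negative absorbances pass through unclamped. Blank offsets are
stored per wavelength in a JSON sidecar.

**Quantification.** Calibration lines are ordinary least squares
(scipy.stats.linregress behind the module surface; an independent
normal-equations oracle lives in the tests). Two points determine the line
exactly, so R² is set to 1 by construction there. Detection limits use the
sample (n−1) standard deviation — the convention for replicate-based
limit-of-detection work — with a configurable multiplier defaulting to 3
(≈99% one-sided confidence). Limits are unit-agnostic: they live on
whatever scale (absorbance or concentration) the replicates are supplied
in. Calibration files are CSV point lists with a JSON header; loading
refits the stored points and rejects files whose stored slope, intercept,
or R² disagree with the refit beyond 1e-9 relative.

## The synthetic forward model

`duobeam.synth` renders the photograph from first principles so every
stage has a ground-truth oracle:

- **LED**: blue die Gaussian at 450 nm (σ 15 nm, amplitude 1.0) plus a
  phosphor Gaussian at 560 nm (σ 60 nm, amplitude 0.9) — typical phosphor
  white-LED shape; these defaults are configuration, not truth claims.
- **Dispersion**: stripe rows span 420–680 nm linearly (the LED's visible
  emission), red at top, ≈1.33 nm/row on the default 256×200 frame.
- **Absorber**: Gaussian ε(λ) centered at 535 nm (σ 40 nm) with peak
  0.15 L·mg⁻¹·cm⁻¹ and l = 1 cm, so the true band-center absorbance is
  exactly ε·c·l, exposed to tests.
- **Camera**: Gaussian channel sensitivities at 610/540/465 nm (σ 35 nm),
  power-law exponent 0.64 by default, additive Gaussian noise (sd 0.01,
  the study condition for all statistical guarantees) applied after the
  power law and clipped to [0,1]. Exposure is normalized so the reference
  stripe peaks at pixel value 0.70 — headroom for beam-imbalance and
  exposure sweeps without clipping.
- **Geometry**: disjoint column spans for the two stripes; optional
  in-plane rotation (validity ±5°, nearest-neighbour resampling;
  localization guaranteed only to ±2°); optional third stripe at a chosen
  fraction of peak vibrancy to emulate stray diffraction orders.

Ground truth returned with every frame: stripe masks, channel-peak rows
and their wavelengths, band-center row, pre-sensor absorbance, dispersion,
and the noiseless frame. Rendering is bit-deterministic in
(configuration, seed); series replicates differ only by noise realization.

**What the generator does not emulate** — and hence what passing tests do
not show about real photographs: Poisson shot noise and fixed-pattern
noise, demosaicing artifacts, JPEG compression, optical blur and stray
light, curved (non-affine) dispersion, turbidity, LED drift with battery
voltage, and second-order spectra overlapping the first order. Real-image
robustness must be established on real frames.

## Verification scales

The statistical suites run at desk scale, chosen as the smallest sizes at
which the estimators stabilize: calibration experiments use 6 levels
(0–5 mg/L) × 1–3 replicates on 256×200-pixel frames; seed sweeps use 20
seeds; the slope-compression law is checked at exponents 0.5, 0.64, and
1.0; blank-invariance at beam imbalances 0.7/1.0/1.3; exposure invariance
at factors 0.5/1.0/1.5. With an ideal sensor and no noise the end-to-end
absorbance agrees with ε·c·l to better than 2% up to A ≈ 2 (the residual
comes from averaging the band over a finite ±5 nm window and one-row
quantization of the anchors).

## Known limitations

- The affine dispersion model cannot represent grating curvature; errors
  grow toward the spectrum ends, farthest from the anchors.
- The blank model assumes the left/right intensity ratio is constant
  between the blank and the measurement; a bumped device invalidates it.
- The tilt guard estimates tilt from column centroids and slightly
  underestimates large rotations; between ~2° and ~3.5° localization
  succeeds with degraded IoU rather than erroring.
- Concentrations outside the calibrated range extrapolate linearly (with
  a warning below zero); no weighted or robust regression is offered.
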