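# Methods

This note records the numerical model behind `holowbc`, the defaults and
why they were chosen, and what the synthetic-data tests do and do not show
about real microscope data.

## Optical model

The package models a Fourier-holographic projector: a phase-only spatial
light modulator (SLM) in the front focal plane of a lens, the
reconstruction in the back focal plane.  Propagation between the SLM and
the reconstruction plane is therefore a single Fourier transform.  All
transforms are centered and unitary (`norm="ortho"`, zero frequency at
index N//2), so Parseval's theorem holds exactly and the error-reduction
argument for the iterative synthesis applies without normalization
caveats.

Default constants (`OpticalConfig`): wavelength λ = 670 nm, SLM
1080 × 1920 pixels at 8 μm pitch, focal length f = 125 mm, camera
2054 × 2452 at 3.35 μm.  The reconstruction-plane sample pitch of an
N-pixel hologram is λf/(N·pitch) ≈ 5.45 μm for the full SLM width; the
physical camera oversamples this, which motivates the observation model
below.

## Iterative hologram synthesis (IFTA)

`run_ifta` alternates between the object plane (amplitude replaced by the
target amplitude, phase kept) and the SLM plane (amplitude set to 1, phase
kept) — the classic Gerchberg–Saxton scheme.  Choices:

* **Initial phase**: uniform random in [0, 2π) from a seed
  (`IFTAConfig.seed`); random initialization is standard and the seed makes
  every run reproducible.
* **Error monitor**: the mean of squared intensity differences
  `mean((I_ref − s·I_NR)²)` where s is the least-squares intensity scale
  (a phase-only reconstruction is defined only up to a global intensity
  factor).  The square root is also reported, since the quantity is
  conventionally quoted as an RMSE.  The trace is non-increasing
  (alternating projections); the suite asserts this to 1e-12 on random
  targets.
* **Phase-convergence statistic**: the RMS of the wrapped difference
  (−π, π] between consecutive SLM phase iterates; the stopping bound
  ε = 0.2 rad.  The run stops on ε, on an error floor of 5e-3, or at the
  iteration cap, whichever comes first; either rule can be disabled.
* **Quantization**: wrapped phase maps linearly to {0..255}
  (round-half-up, so π ↦ 128); level 255 dequantizes to 2π, i.e. the same
  physical phase as level 0.  Quantization changes the reconstruction
  error only marginally (the suite bounds the degradation at 10×; measured
  ≈ 1×).
* **Precision**: a float32 target runs the whole loop in single precision
  (complex64), halving time and memory for the 7680 × 4320 frame; the
  convergence statistics are orders of magnitude above float32 resolution.

At the full padded scale the run reaches an intensity error of ~1e-5 and a
phase step of ~0.01 rad at n = 60, comfortably inside the ε = 0.2 rad
convergence criterion.

## Hologram modulation and the focal stack

Component m (cell body, edges + nucleus, nucleus) is modulated by a tilt
`R_m = exp(ik[sin α_m ν_i + sin β_m ν_j])` and a defocus chirp, and the
displayed hologram is the argument of the complex sum of the modulated
unit-modulus fields.  Pixels where the sum is exactly zero receive phase 0
(a measure-zero tie-break that only occurs analytically).

**Chirp convention.**  The defocus factor is implemented as the standard
Fresnel transfer `exp(iπλz|f|²)` evaluated at the spatial frequency that
an SLM coordinate ν addresses in the Fourier-lens geometry, f = ν/(λf_L).
Written out: `exp(iπ z |ν|²/(λ f_L²))`.  With z in the numerator, z = 0 is
the exact identity and chirps compose additively
(χ(z₁)·χ(z₂) = χ(z₁+z₂)), both pinned by unit tests.  Reconstruction at a
scanned distance z multiplies by the conjugate chirp, which exactly
cancels the defocus of components with z_m = z.  A quadratic phase taken
literally in meters of SLM coordinate would amount to ~1e-13 rad across
the aperture for centimeter distances — physically inert — so the
frequency-coordinate reading is the only one that produces the depth
behavior the display method relies on.

**Tilts.**  A component's lateral shift Δu at its reconstruction plane
determines the tilt through sin α = Δu/z_m (an in-focus component,
z_m = 0, cannot be shifted).  By the discrete Fourier shift theorem the
reconstruction moves by sin α · N · pitch/λ pixels; the suite verifies the
measured centroid shift against this prediction to better than one pixel,
including fractional shifts.

**Focus score.**  Sharpness within a region of interest is the variance of
the Sobel gradient magnitude of the intensity, after Gaussian smoothing
(σ = 2.5 px) and normalization by the squared mean ROI intensity.  The
smoothing is essential: phase-only reconstructions carry residual speckle
whose gradients are large at *every* plane, and an unsmoothed gradient
score does not peak at the focus.  With smoothing, each component's score
peaks exactly at its own z_m across a 21-plane scan (asserted in the
suite for the three-component cell/edges+nucleus/nucleus hologram).

Default z spacings in examples (~0.08 m at a 256-pixel aperture) are
chosen so neighboring planes are visibly separated at desk scale; they are
configuration, not physics.

## Speckle reduction and the observation model

The reduction chain: zero-pad the target to 4× the SLM window → synthesize
one 4320 × 7680 hologram → split into sixteen 1080 × 1920 tiles (row-major;
the average is order-invariant) → average the sixteen reconstructed
intensities.  Each tile carries a different subset of the padded frame's
spatial frequencies, so its reconstruction is an independent speckle
pattern; averaging N independent patterns reduces C = σ/μ like 1/√N.

**Observation model.**  Reconstructed intensities are sampled at
`pad_factor`× the hologram's native grid: the unit-modulus SLM field is
embedded centered in a 4× frame before transforming.  The native grid
places exactly one speckle grain per sample, which *hides* the
inter-sample speckle that a real camera resolves (the camera pitch is
finer than the reconstruction pitch).  Evaluated on the native grid, a
well-converged unpadded hologram looks nearly speckle-free and the
before/after comparison is meaningless; on the oversampled grid the
baseline shows the strong speckle familiar from phase-only projection
(C ≈ 0.8–1.1 on the cell support) and the sixteen-tile average reduces it
several-fold.  Both arms of `speckle_pipeline` use the same observation
model, and the sixteen-seed averaging study measures a contrast-reduction
factor of ≈ 3.6 (theory √16 = 4; the shortfall is residual structure
common to all patterns).

Statistics are computed over the bright support of the target (intensity
above 50% of maximum), since contrast over dark background is undefined.
σ is the population standard deviation of the least-squares-scaled
intensity.  Whether the sixteen projections are summed or averaged only
changes a global scale; averaging keeps intensities normalized.

## Segmentation

The stages follow the thresholding recipe exactly: green channel →
percentile stretch → binarize at 70% of I_B → remove small components →
fill holes → Gaussian smoothing → Sobel edges.  Open points resolved as
follows:

* **Polarity**: stained cells are darker than the film background, so the
  foreground is the *below*-threshold set; exposed as
  `dark_foreground` for inverted imagery.  With this polarity the mask
  grows monotonically with the threshold fraction
  (mask(t₁) ⊆ mask(t₂) for t₁ < t₂), which the suite asserts.
* **I_B**: "bright-area intensity" is taken as the 99th-percentile
  intensity — robust to hot pixels; the percentile is configurable.
* **Histogram adjustment**: linear stretch of the 1st..99th percentiles to
  [0, 1].  A near-degenerate histogram (range < 0.05) is passed through
  unchanged: stretching a blank, noisy frame would amplify sensor noise to
  full range and fabricate foreground.
* **Connectivity**: 8-connected components; holes are filled with an
  8-connected background flood (only fully enclosed holes fill).
* **Gaussian window**: side 15 with σ = window/6 ≈ 2.5, so the kernel is
  effectively supported by the window; reflective borders; the smoothed
  mask is re-binarized at 50%.  A single isolated pixel vanishes under
  this filter (center weight ≪ 0.5).
* **Component floor**: 50 000 px matches full-resolution microscope
  frames; `SegmentationConfig.rescaled(f)` scales it by f² for
  downsampled fixtures.
* **Nucleus**: the package adds a second, lower threshold
  (`nucleus_threshold_fraction`, default 0.40·I_B) restricted to the cell
  mask to isolate the nucleus — the darkest stained region — for
  morphometry; the original recipe segments only one structure at a time.

If several components survive cleaning, the largest is kept, so a result
always holds a single cell.

## Morphometry

Axis lengths use the moment-equivalent ellipse (the standard
region-properties convention), times the μm-per-pixel calibration; areas
are pixel counts times calibration².  Percent increases are reported at
two decimals.  The built-in reference table of measured normal and cancer
WBCs reproduces the published comparison figures exactly at that rounding
(41.69% mean major-axis increase; 187.16 / 67.97 / 125.04% per-cell area
increases).  Two bookkeeping notes: those three per-cell figures follow
the *cell-area* column of the reference table even though the source text
labels them nucleus areas (the nucleus column gives different ratios), and
the printed 33.02% mean minor-axis increase back-computes to 32.97% from
the tabulated values; the implementation reports what the numbers give and
exposes both columns rather than guessing intent.

## Synthetic scenes: what they emulate and what they do not

The generator draws each cell as a rotated ellipse (cytoplasm) with a
kind-specific nucleus: two lobes for basophils and eosinophils, four for
neutrophils, a kidney shape for monocytes, a round nucleus nearly filling
the cell for lymphocytes (consistent with the reference table's equal
nucleus and cell areas), and an enlarged, radially perturbed oval for the
cancer lymphocyte (axes scaled 1.42× / 1.33×, the reported mean
enlargement, so morphometry comparisons have a built-in effect).
Granules are small ±0.15 speckles over the cytoplasm of granulocytes.
Colors: background (0.95, 0.93, 0.90), cytoplasm (0.95, 0.65, 0.75),
nucleus (0.45, 0.20, 0.55) — chosen so the green channel separates nucleus
from background more strongly than red or blue (asserted per scene), which
is the property the segmentation exploits.  Noise is additive Gaussian
(default σ = 0.01 of full range, a mild sensor-noise level), clipped to
[0, 1]; scenes declare their own calibration (default 0.1 μm/px, typical
of a 60X objective with a fine camera).

Passing on these scenes demonstrates the pipeline's internal consistency
(exact ground truth, known geometry), not robustness to real stain
variability: no uneven illumination, focus blur, touching cells,
red-cell background clutter, or stain batch effects are modeled.  Cells
never overlap by construction, so per-cell ground truth is unambiguous.

## Problem sizes

The test suite runs every stage at reduced scale — 68 × 120 to 270 × 480
SLM windows, with the component floor rescaled accordingly — and the
convergence check at one-quarter linear scale (1080 × 1920 padded frame).
`scripts/acceptance.py` repeats the convergence run at the full
7680 × 4320 frame in single precision (~10 min, ~2 GB on one core).

## Known limitations

* The numerical reconstruction is an idealized coherent model: no SLM
  pixel fill-factor, flicker, curvature, polarization leakage or camera
  noise, so absolute σ/C/PSNR values are not comparable to optical-bench
  measurements — only directions of change and convergence statistics are.
* Diffraction between tilted planes is paraxial; occlusion between
  overlapping displayed components is not modeled.
* The speckle observation model fixes the oversampling factor to the pad
  factor so both comparison arms share one grid; other camera pitches
  would need resampling.
* Segmentation targets one cell per (cropped) field; multi-cell instance
  segmentation is out of scope.
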