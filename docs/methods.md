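# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind each `ecmorph` module, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Units and conventions

Heights in nm, lateral distances in µm (pixel pitch `pixel_size_um`),
forces in pN, positions along force curves in nm with larger values further
from the surface, energies in J (1 pN·nm = 10⁻²¹ J). Height-map rows are
the slow scan axis, columns the fast axis. FFT spectra are center-shifted
with the center at index ⌊dim/2⌋.

## Fibrosity index

The index summarizes how strongly the surface texture of a cell is
dominated by parallel ridges (stress fibers pressing against the membrane).
Pipeline, in order:

1. **Scan-line leveling** — subtract the median of each fast-scan row.
   Constant per-row offsets, the dominant AFM raster artifact, are removed
   exactly.
2. **Fourier bandpass + stripe notch** — Gaussian transfer functions pass
   spatial scales between `bandpass_small` (default 3 px, pixel noise) and
   `bandpass_large` (default 40 px, roughly cell-scale relief at a
   20 µm/128 px field; stress fibers at ~1.25 µm spacing sit comfortably
   inside the band). Residual stripe energy is attenuated ≥ 99% in a
   Gaussian notch of half-width `stripe_halfwidth` (2 px) along the
   frequency axis carrying the stripes; the DC sample is left alone and is
   discarded later by the radial band. Soft (Gaussian) cutoffs avoid
   ringing.
3. **Gaussian pre-smoothing** (σ = 1 px), **Sobel gradient magnitude**,
   **Gaussian post-smoothing** (σ = 1 px) — the edge image emphasizes
   ridge boundaries, whose orientation carries the anisotropy.
4. **Radial Hann taper** *w(n) = 0.5 − 0.5·cos(π(1 − n/N))* with *n* the
   pixel's distance from the image center and *N* half the smaller image
   dimension, clamped to 0 outside the inscribed circle. The ramp-from-1-
   to-0 form is not the standard separable Hann window; it is implemented
   as a *radial* taper because only an isotropic window leaves the angular
   statistic unbiased — a separable window would itself inject cardinal
   anisotropy. `window="separable-hann"` provides the conventional
   alternative.
5. **FFT magnitude spectrum**, center-shifted, then Gaussian-smoothed
   (σ = 1 px). Linear magnitude is the default scale; `power` and `log`
   are selectable. Magnitude was chosen because it preserves exact scale
   equivariance (heights × c ⇒ index × c), which makes the index
   interpretable across amplitude regimes and is asserted in tests.
6. **Angular profile** — mean spectral magnitude per angle bin
   (default 2°) over the annulus `radial_band` (default 3 to
   min(dim)/2 − 1 px), folding the point-symmetric half-planes onto
   [0°, 180°). Empty bins are reported missing (NaN), never zero.
7. **Cardinal exclusion** — bins whose centers lie within ±5° (default) of
   0° or 90° are flagged and excluded: the raster scan imprints energy on
   the cardinal axes regardless of the actual texture.
8. **Index** — standard deviation of the included bin means, population
   denominator (N) by default (`sd_ddof` configurable).

A constant map has an identically zero edge image and index 0. The
angular-binning stage is verified against a per-pixel brute-force oracle to
1e-10 relative; the full windowing-to-SD tail against an independent loop
implementation to 1%.

The bandpass cutoffs, smoothing σs, bin width and exclusion half-width are
declared defaults — reasonable for ~20 µm scan fields — not values with
independent physical meaning; all are recorded in the result object.

## Force-curve analysis

**Baseline.** A least-squares line over the off-contact fraction
(default 30%) of a segment; `noise_sd` is the RMS residual and scales both
the contact threshold and the adhesion zero-band.

**Contact point.** Walking from the off-contact end, contact is flagged
where the corrected force exceeds `k_sigma`·noise_sd (k_sigma = 3) for
`run_length` = 10 consecutive samples; no such run raises `NoContactError`
(flat or failed curve — e.g. a zero-stiffness ramp, or a slope so shallow
the force never clears the noise band within the ramp). Because the
flagged sample lies where the force has already cleared the band — roughly
threshold/slope *past* the true contact — the position is refined by a
hinge fit: the piecewise model F = max(0, k·(x₀ − x)) is fitted by least
squares over the whole corrected approach (closed form per candidate
breakpoint via prefix/suffix sums) and the SSE-minimizing breakpoint is
returned. This is exact on noiseless ramps whose kink lies on the sample
grid and nearly unbiased under noise (~10–20 nm median error at the
default study conditions), where the raw run-start is biased hundreds of
nm deep. The unrefined positions remain available (`refine="sample"`,
`"interpolate"`).

**First-slope stiffness.** Least-squares slope (with intercept) of
corrected force vs. indentation depth over `window_nm` = 200 nm past the
contact point, reported in pN/nm. The window default suits a 100 nm
trigger-threshold regime; it is configurable and always reported. The
intercept makes the slope exactly invariant to horizontal translation and
to residual contact-detection offset on linear-regime curves. This is a
deliberate linear fit, not a Hertz/Sneddon modulus: the readout *is* the
slope.

**Adhesion.** On the baseline-corrected retraction, samples within
±k_sigma·noise_sd of the baseline contribute nothing, and an adhesion event
is recognized only when ≥ `run_length` consecutive samples sit below the
band (mirroring contact detection). Without a sustained event both metrics
are zero — isolated noise excursions below the band are never rectified
into spurious energy, and a dip shallower than the band yields exactly 0.
Given an event: maximal pulling force = |most negative corrected force|,
energy = trapezoidal integral of the below-band negative force over
retraction distance. Only negative-force work is integrated (physical
adhesion energy); positive-force regions are excluded by construction.

**Aggregation.** Per-cell means with an inclusion flag (≥ 6 curves/cell
for stiffness, ≥ 20 for adhesion, configurable), ready for the
group-comparison harness.

## Protrusion detection

The local cell surface is estimated by grey-scale morphological opening
followed by median smoothing with window `window_um` (default 3 µm; must
exceed the protrusion footprint and stay below cell-scale relief, at least
3 px). Opening rides the envelope minima — a bias of roughly
slope·window/2 under tilt — so the background is recentered to make the
residual median zero. A boundary strip of about one window width retains
an edge artifact of the opening; protrusions touching the field border are
correspondingly less reliable.

Protrusions are connected components (8-connectivity default) of
residual ≥ `threshold_nm` (default 120 nm, the conventional
above-surface criterion) with ≥ `min_area_px` = 4 pixels (rejects
single-pixel spikes). Volume integrates the *residual* over region pixels
— the physical bump volume above the local surface, not the volume above
the threshold plane. For a Gaussian dome of height h and width σ the
above-threshold volume has the closed form 2πσ²(h − t), which the detector
reproduces within a few percent at 256-px sampling of a 20 µm field.

This detector deliberately replaces proprietary learned surface-object
classifiers with a transparent threshold+geometry rule; results are
comparable in kind (counts, volumes) but not calibrated to any
classifier's output, and the output metadata says so.

## Fluorescence quantification

**PLA dots.** Rolling-ball background subtraction (radius 50 px default;
the ball is fitted on a 3×3 median-presmoothed copy so it rides the
background rather than the noise floor), binarization, rejection of
islands < 4 px, Gaussian blur of the mask (σ = 1 px), prominence-gated
maxima (h-maxima at 10% of the blurred mask's range — the analogue of an
ImageJ "find maxima" noise tolerance), and watershed splitting seeded at
those maxima. The default binarization is `robust-sigma`: threshold at
median + 5·(MAD-based σ) of the subtracted image. Global histogram
methods (Otsu, Li, Yen, triangle — all selectable) place their threshold
inside the background mode when dots occupy only ~1–2% of pixels and then
report thousands of false maxima; the robust noise threshold is stable in
exactly that sparse-foreground regime, and falls back to Otsu on
noise-free images (zero MAD), where a bimodal histogram is well defined.
Two ideal dots merge below ~2.5σ separation (the generator's
Rayleigh-like resolvability criterion); at 4σ the watershed splits them.
Per-coverslip means feed the group comparison.

**Fiber diameter.** Intensity profile along a probe line (sub-pixel linear
interpolation, step ¼ px); local background and noise from the profile's
outer quartiles; bases at the outermost crossings of background + k·noise
(k = 3) around the central peak, with sub-step interpolation — or of
background + `band_fraction`·amplitude when a fractional band is wanted
(e.g. a 10% band on a Gaussian profile of width σ gives the closed form
2σ√(2 ln 10)). A noise-band base is used because a true zero crossing is
undefined under noise; it makes the measured diameter mildly
amplitude-dependent, which the fractional-band option removes.

**Fiber length.** Multi-scale Sato tubeness filter → Otsu threshold →
skeletonization → per-component geodesic length (axis steps 1 px,
diagonals √2, diagonal shortcuts already bridged by axis steps skipped).
Crossing fibers merge into one component whose length approximates the sum
of the individual lengths; junction geometry contributes a few percent
error. Skeletons overshoot fiber tips by about the fiber half-width.

**Channel ratios.** Each stain's integrated above-median intensity divided
by its own DAPI integrated intensity (proxy for the amount of cell
material), then the ratio of the two normalized signals. Per-nucleus-count
normalization (`normalization="nuclei"`) is provided because
"normalized to DAPI" is ambiguous between the two readings. Integrated
intensities keep the ratio exactly linear in either channel's gain.

## Statistics

**2^(−ΔΔCT).** ΔCT = Ct(gene) − mean Ct of the housekeepers (defaults
*Gapdh*, *Gusb*) per sample; ΔΔCT = ΔCT − mean reference-group ΔCT per
gene; fold change 2^(−ΔΔCT). The output keeps the ΔCT column because
hypothesis tests belong on that (approximately normal) scale, not on fold
changes. Adding any constant to all Ct values of a sample cancels exactly.

**Differential filter.** Per-protein two-sided t-test on log₂ abundances —
Welch by default (robust to unequal variances; the classic equal-variance
test is selectable), unpaired — BH adjustment across testable proteins,
pass = (q ≤ 0.01) ∧ (|log₂FC| > 0.5, i.e. fold change ≥ 1.4) ∧
(≥ 2 peptides). Proteins with degenerate tests (constant abundances) get
NaN p-values and never pass. The BH stage is verified against a step-up
oracle implemented directly from the definition.

**Group comparison.** Normality per group at α = 0.05 with
D'Agostino-Pearson for n ≥ 8 and Shapiro-Wilk below (the moment-based
omnibus test is unreliable at very small n). All groups normal →
t-test (2 groups) or one-way ANOVA + Bonferroni-corrected pairwise t
contrasts; otherwise Mann-Whitney U or Kruskal-Wallis + Dunn's z-tests
(tie-corrected, Bonferroni-adjusted). Groups of n < 3 cannot be screened:
the harness takes the nonparametric route and records a warning. The
report always states the route. Null calibration of the final p-value is
within [0.03, 0.07] at nominal 0.05 for both data regimes (the routing
step makes the parametric branch very slightly conservative, since
normality outliers are diverted to the rank test).

## Synthetic data: what it does and does not emulate

Generators draw from independent per-component streams spawned from one
seed (`SeedSequence` spawn keys), so outputs are bit-reproducible and
adding a generator never perturbs existing fixtures. Study-condition
defaults: 128-px height maps at 0.156 µm/px (a 20 µm × 20 µm = 400 µm²
field), fiber spacing 1.25 µm and amplitude 30 nm, domes of 200 nm × 0.5 σ
µm, 2 µm force ramps at 2048 samples with a 0.03 N/m probe, triangular
adhesion dips (the analysis uses only minimum force and area, both of
which a triangle makes analytic), Gaussian dots of σ = 2 px at peak SNR
~10 over a Poisson background, protein tables of 1000 rows with 50 planted
|log₂FC| = 1.5 effects at 0.25 log₂ within-group SD, Ct tables with
sample-wide shifts tracked by the housekeepers.

Not emulated: realistic cell outlines and cell-scale curvature, cantilever
dynamics and hydrodynamic drag, worm-like-chain tether rupture, optical
PSF structure beyond Gaussian spots, spatially correlated background,
segmentation of touching cells. Passing tests therefore demonstrate
algorithmic correctness against known ground truth — recovery of planted
parameters, closed forms, invariances, calibration — not performance on
real micrographs, where parameter defaults (bandpass, thresholds, windows)
would need adjustment to the instrument and magnification.

## Numerical choices and degenerate inputs

- Spectrum center at ⌊dim/2⌋ (FFT-shift convention); even and odd
  dimensions both supported and tested.
- Angular bins must divide 180°; empty bins are NaN and excluded from the
  SD; an all-excluded profile is an error, as are non-finite filter
  outputs.
- Baseline fits require ≥ 10 samples; stiffness fits ≥ 10 in-window
  samples; curve segments ≥ 50 samples with strictly monotone positions.
- Noiseless curves collapse the noise band to zero width; exact zeros then
  count as baseline, so a flat curve is "no contact" rather than a
  zero-slope fit.
- Fiber periods below 2 px are rejected (aliasing); spot placement that
  cannot satisfy the minimum separation is rejected after a bounded number
  of attempts; protein/Ct groups need ≥ 2 samples.
- Protrusion summaries report a `None` mean volume for empty sets rather
  than zero.

## Limitations

- The fibrosity index is a relative measure; absolute values depend on the
  declared filter defaults and on image size, so only within-protocol
  comparisons are meaningful.
- The hinge contact refinement assumes an approximately linear post-contact
  regime; strongly Hertzian curves would need the windowed variants.
- Stiffness recovery degrades as slope/noise falls; at 0.01 pN/nm and
  10 pN baseline noise the contact threshold is never reached inside a
  2 µm ramp and the pipeline reports "no contact" rather than a number.
- Skeleton-based fiber lengths mildly overshoot at fiber tips and
  undercount at dense junctions.
- The protrusion detector is not calibrated against learned classifiers;
  threshold and window defaults are conventions, not fitted values.
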