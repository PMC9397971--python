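# Methods

This note documents the models, conventions and numerical choices behind
`mubkit`, in the spirit of the model-documentation pages of simulation
and statistics packages. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Image and ROI conventions

Images are 8-bit grayscale rasters with row 0 on the superficial (skin)
side; the pixel at row *r* images depth `r * row_spacing_mm`. Pixel
centres sit at integer coordinates and polygons are given in pixel
units; a mask pixel is "inside" a polygon when the polygon **covers**
its centre (boundary included). These conventions make rasterised pixel
counts exactly reproducible, which the tests exploit (brute-force
point-in-polygon oracles).

Acquisition constants of the reference protocol fix the field of view:
depth 2 cm (so `row_spacing = 20 mm / rows`) and a 5-cm probe footprint
(default `col_spacing = 50 mm / cols`). Probe frequency (12 MHz) and
gain (85) are metadata only — they do not enter the rendering model
beyond the point-spread-function scale below.

**Lateral trimming.** The analysed ROI is a contiguous column band of
fixed physical width — 10 mm (longitudinal) / 5 mm (transverse) —
`round(width / col_spacing)` columns wide, centred on the column
centroid of the outlined mask with ties broken toward the lower column
index. The painful-site skin mark that centred the probe leaves no
digital trace; since the probe was centred on the mark, the mask
centroid is the best available surrogate. Trimming is idempotent and
never adds pixels; an ROI narrower than the target width raises an
error naming the shortfall in mm.

## 2. Biomarkers

* **Mean thickness** averages the per-column *extreme-row extent*
  (inferior − superior + 1 rows) over the band, times the row spacing.
  The extent (envelope) definition means interior mask holes do not
  shrink thickness — thickness is a property of the epitenon-bounded
  outline, not of the mask area. An area/width variant
  (`mean_thickness(..., method="area")`) is provided because the two
  definitions differ for non-rectangular ROIs and the source program's
  choice is not documented.
* **Echogenicity** is the arithmetic mean of raw 8-bit gray levels over
  the mask; no normalisation is applied (the acquisition protocol holds
  gain and TGC constant precisely so that raw levels are comparable).
* **Homogeneity** is computed from a gray-level co-occurrence matrix
  that respects the ROI mask: ordered pixel pairs (p, p+offset) count
  only when both pixels are inside the mask. Offsets at distance d:
  0° = (0,+d), 45° = (−d,+d), 90° = (−d,0), 135° = (−d,−d); symmetric
  accumulation and normalisation to sum 1 are the defaults. Intensities
  are linearly binned to 64 levels (`levels*I // 256`). The statistic is
  Σ P(i,j)/(1+(i−j)²), which is 1 iff all mass is diagonal; the
  alternative 1/(1+|i−j|) kernel is available via `GLCMSpec(kernel=...)`.
  Level count, distance, symmetry and kernel are deliberately exposed
  because the upstream acquisition study does not print them; 64 levels
  keeps matrices usefully dense at ~100×100-px ROIs while preserving
  speckle contrast.

  90° is the depth axis — perpendicular to the fibre direction in
  longitudinal images, where the transducer is aligned with the fibres.
  Longitudinal homogeneity is evaluated at 90° only (the striation
  direction carries the signal); transverse homogeneity is the
  multidirectional mean over all four angles.

Triplicate frames per plane/side are averaged field-wise; averaging two
frames is accepted with a warning, mixed planes or sides are an error.

## 3. The synthetic world

The simulator's purpose is to give every downstream stage a ground
truth, at the published cohort's operating point.

**Geometry.** Longitudinal: a horizontal band of the configured
thickness starting `superior_margin_mm` (default 4 mm) below the skin.
Transverse: a flattened-oval cross-section (superellipse of exponent 4,
default semi-width 7.5 mm). The exponent-4 oval is used instead of a
true ellipse because the Achilles cross-section is a flattened oval and
because an ellipse's chord taper would alone bias the 5-mm-band mean
thickness by ~2%, confounding the recovery tests; the superellipse
taper is below 0.5%. Membership uses the half-open band
`[superior, superior + thickness)` evaluated at pixel-centre depths, so
rendered band heights equal `thickness/row_spacing` rows ± 1.

**Texture.** Longitudinal fibrillar architecture appears as a sinusoidal
striation across depth (period 0.8 mm, amplitude `fibril_contrast`);
transverse fibril cross-sections are sub-resolution dots, rendered as
isotropic Gaussian-correlated noise at the PSF scale with the same RMS
as the sinusoid. The texture is demeaned per column inside the tendon,
so the noise-free intra-tendon mean is exactly `mean_echo` regardless
of how many striation periods fit the band.

**Speckle.** Multiplicative field `1 + s·(R/E[R] − 1)` with
R ~ Rayleigh: `s = 0` is exactly noise-free, `s = 1` is fully developed
mean-normalised Rayleigh speckle (CV ≈ 0.52). A literal Rayleigh *scale*
parameter cannot serve as a noise dial because the Rayleigh CV is
scale-invariant. The field is spatially correlated by a Gaussian of
FWHM `psf_mm` (default 0.3 mm, the resolution cell of a 12-MHz probe),
because fully developed speckle decorrelates at the system PSF, not per
pixel.

**Defaults = the published cohort.** Asymptomatic thickness/echogenicity
means and between-subject SDs are the published Table of side means
(5.15 (1.30) mm / 77.0 (15.7) longitudinal; 5.17 (1.13) / 83.7 (15.4)
transverse). Symptomatic effects are multiplicative thickening ×1.299
(long.) / ×1.253 (transv.) and echogenicity drops 7.4 / 5.4, i.e. the
published symptomatic means. Texture parameters are not published;
`fibril_contrast = 8`, `speckle_scale = 0.15` and contrast drops
0.8 / 1.6 were calibrated **once** so that extraction at a 256-px
reference raster reproduces the published longitudinal homogeneity level
(~0.595) and the published symptomatic side-difference (+0.023) in both
planes, and were then frozen.

**Severity and clinical measures.** One latent severity per subject,
N(1, 0.35) clipped to [0.2, 2.5] (bounded away from zero because every
participant is clinically symptomatic by the inclusion criteria),
scales all three symptomatic shifts and drives each clinical outcome
linearly: `y = mean + coef·(severity − 1) + ε`, rounded/clipped to the
instrument range (VISA-A items 0–10 / Q8 0–30, LEFS 0–80). Per-side
clinical measures (lunge distances, peak moments) share a subject-level
base value plus independent per-side measurement residuals, with a
severity-scaled asymmetry fraction equal to the published DIs — so a
zero-effect configuration makes the two sides exchangeable (the null
world used for calibration tests). Default outcome coefficients
(−2 per severity unit for VISA items, −5 for Q8/LEFS) give mostly
negligible-to-low biomarker–clinical correlations (population r ≈ 0.2),
mirroring the reference study's predictive-validity finding; they are
configuration, not measurement. `residual_sd_for_r` solves the residual
SD for any target population correlation against a severity-proportional
biomarker (the thickness DI is exactly proportional to severity, since
the subject's baseline thickness cancels in the index). Strength and
LEFS are missing outside the last `subgroup_size` subjects (protocol
update replicated as missingness by subject index).

**What the simulator does not emulate**, and hence what a green test
does not establish: anisotropy artefacts, attenuation/TGC depth trends,
refraction and reverberation, off-axis probe placement, manual-outline
variability (ROIs are ground-truth polygons), neovascularisation, and
any nonlinearity in the severity–outcome links. Homogeneity's absolute
level depends on the raster, quantization and speckle CV; only its
ordering and side-differences are claims of the stated world. The
per-subject transverse-homogeneity discrimination rate saturates near
~88%, not 95%, because the published transverse texture effect (+0.023)
is small relative to extraction noise for low-severity subjects — the
property test therefore claims ≥95% per subject only for thickness,
echogenicity and longitudinal homogeneity, plus the group-level
direction in the transverse plane.

## 4. Statistics

* Paired side comparisons: Shapiro–Wilk on the paired differences at
  α = 0.05 gates paired Student's *t* (normality not rejected) vs
  Wilcoxon signed-rank (zero differences dropped, mid-rank ties).
* Hedge's g uses the pooled SD — `sqrt(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2))`,
  reducing to `sqrt((s₁²+s₂²)/2)` at equal n — with the
  J = 1 − 3/(4(n₁+n₂−2)−1) small-sample correction; this (independent-
  groups) form reproduces the published effect sizes, so it is the
  default even for paired data. Magnitude bands: >0.2 small, >0.5
  medium, >0.8 large.
* The Difference Index for group rows is computed from group means
  (primary; reproduces 10 of 11 published values) and also as the mean
  of per-subject DIs (labelled variant, emitted alongside) because one
  published row is only consistent with per-subject averaging.
* Correlations: pairwise deletion; Pearson when both marginals pass
  Shapiro–Wilk at α = 0.05, Spearman otherwise (the strictest consistent
  reading of the protocol's per-family rule; overridable via the
  `normality` argument). Strength bands are half-open with boundary
  values assigned upward (0.3 → "low", 0.9 → "very_high") since the
  verbal definitions overlap at the boundaries.
* Group-vs-subgroup rows use independent two-sample *t* (continuous) or
  Pearson chi-squared without continuity correction (categorical),
  knowingly treating an overlapping subset as independent groups — the
  report carries a note to that effect.
* No multiple-testing correction by default (protocol: α = 0.05
  throughout); `bh_correction=True` re-flags significance with
  Benjamini–Hochberg-adjusted p-values, leaving raw p-values untouched.
* Degenerate inputs raise typed errors (all-zero differences, zero
  variance, zero pooled SD, zero DI denominator); per-subject DI series
  map zero denominators to NaN; entirely missing clinical columns yield
  placeholder report cells (`n_pairs`, `strength="undefined"`) rather
  than failures.

## 5. Numerical and testing notes

* Determinism: every stochastic step derives from
  `numpy.random.SeedSequence` children of a single seed; re-running any
  command with the same seed reproduces CSV and PNG files byte-for-byte.
  Per-frame seeds hash (cohort seed, subject, side, plane, frame).
* The discriminative acceptance simulation runs 200 cohort replicates
  at a reduced 64×64 raster (0.3125 mm/row) to fit a single-CPU budget;
  the ground-truth-recovery tests run at 320 px, and the per-subject
  discrimination property at 256 px (the calibration raster).
* The statistical-calibration tests run at table level (generative
  biomarker columns, no rendering): type-I error of the gated paired
  and correlation tests over 2,000 null cohorts, and recovery of a
  configured moderate association at n = 500. Image-extraction noise
  attenuates correlations slightly; that attenuation is exercised by the
  image-level discriminative simulation, not by the calibration tests.
* The masked GLCM is checked against brute-force pair enumeration and,
  on full rectangular masks, against `skimage.feature.graycomatrix`
  (whose angle convention measures from a downward row axis, so its π/4
  equals this package's 135° under symmetry).
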