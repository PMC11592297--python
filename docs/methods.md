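# Methods

This note records the models, conventions and numerical choices behind
sonoderm, in the order data flows through the package.

## Coordinate and rasterization conventions

Frames are `(row, column)` arrays with row 0 at the skin surface and depth
increasing downward. A layer is bounded by two polylines that are
functions of the column; its region is the half-open band
`upper(c) ≤ row < lower(c)`, so vertically adjacent layers partition the
image with no double-counted pixels. Edges are rasterized by linear
interpolation between polyline vertices at integer columns, rounding half
up. Half-up rounding (rather than banker's rounding) is chosen so toy
geometries produce bit-stable, hand-checkable values.

Thickness is computed per column as `(lower − upper) · Δz` and reported as
the column mean; the thickness variation index (TVI) is the sample SD
(n−1) of that profile. A single-column profile reports SD 0 by
convention. Statistics are computed on the integer pixel counts and
scaled to mm afterwards, so constant profiles have exactly zero SD.

## Morphology

* **Surface roughness (SR)** is the sample SD of the rasterized upper-edge
  rows, in pixels. The estimator choice (SD rather than mean absolute
  deviation or RMS-about-fit) is a design decision; SD matches the
  magnitudes typical for a ~10 px entry echo band. A mm accessor exists
  but pixels are the reported unit.
* **PAR** treats the mask as a union of closed unit pixel squares and
  divides the total length of exposed square edges by the pixel count.
  No diagonal corner cutting: a 10×100 rectangle has perimeter 220
  exactly. This makes small-shape values exact rationals for tests.
* **ACR** divides the pixel count by the area of the convex hull of the
  same square union (hull of all square corners), capped at 1. Convex
  pixel regions score exactly 1; an L-triomino scores 6/7.

PAR and ACR are defined for any layer but are clinically meaningful for
the entry echo, whose jaggedness they summarize together with SR.

## Echogenicity and texture

Pixels are low-echogenic below 30, medium in [50, 150] (inclusive), high
above 200. The gaps 30–49 and 151–200 are deliberately unclassified, and
each ratio divides by all pixels of the layer, so LEP+MEP+HEP ≤ 1 with the
unclassified remainder making the partition exact.

MPI is the arithmetic mean, PIV the sample SD (n−1), EPI the Shannon
entropy (base 2) of the raw 256-bin histogram divided by 8 so that a
uniform histogram scores 1. No histogram smoothing is applied.

GLCM features use full 256-level quantization, distance 1, offsets
(0,1), (−1,1), (−1,0), (−1,−1) for 0°/45°/90°/135°, symmetric counting,
and — the operative choice — only pixel pairs with *both* members inside
the region mask, which keeps layer-boundary gradients from contaminating
within-layer texture. Per-direction quadruples are first-class (clinical
reports sometimes find only some directions significant); the mean over
available directions is auxiliary. A direction with no valid pair is
reported absent, not zero. Correlation of a zero-variance (constant)
region is defined as 0 and flagged degenerate rather than erroring,
because constant test regions must be legal inputs. These GLCM parameters
are documented defaults: published feature tables rarely state
quantization/distance/direction choices, so exact numerical comparability
with any given clinical table is not claimed.

## Phantom generator

The generator emulates what a 20 MHz dermatologic scan of a three-layer
skin shows, not the acoustics that produce it (no point-spread function,
attenuation or shadowing — a stated non-goal):

* **Geometry.** Default 256×384 px at 0.02 mm/px axial spacing; device
  pixel pitch is generally unpublished (axial *resolution* ≈ 80 µm is not
  a pixel spacing), so spacing is configurable. Defaults put a 0.1981 mm
  entry echo at ≈10 px and a 0.4039 mm SLEB at ≈20 px — realistic pixel
  counts for the published thickness scale.
* **Surface roughness.** Gaussian white noise convolved with a Gaussian
  kernel (correlation length, default 8 px) applied to the entry-echo
  upper edge. The kernel is normalized to unit L2 norm so the marginal SD
  of the edge equals `roughness_amplitude_px`; the finite-width *sample*
  SD an extractor sees is slightly smaller because correlated noise over
  a finite window loses low-frequency variance to the sample mean.
* **Lower boundaries** follow the upper edge plus the layer thickness plus
  independent smoothed jitter (`thickness_jitter_px`, default 2 px
  ≈ 0.04 mm at default spacing, matching the TVI scale of a treated
  cohort). This keeps SR and TVI separately controllable.
* **Speckle.** Multiplicative gamma noise, shape k (mean 1), on the layer
  mean, clipped to [0, 255] after half-up rounding — the standard B-mode
  texture surrogate; k controls PIV ≈ MPI/√k. Default k = 3 gives
  visually plausible speckle across all three layers with a single
  scalar; `None`/∞ disables noise, making each layer a constant-intensity
  band (used heavily by exact tests). Default layer means (entry 159,
  SLEB 27, dermis 40.5) follow the week-0 MPI scale of an actinic
  keratosis cohort.
* **Background** (above the surface, below the dermis) is 0 — anechoic
  gel/far field.

Cohorts draw latent per-marker parameters (thicknesses, layer means,
roughness) around the base spec using fixed between-marker spreads
(`BASELINE_SPREADS`, chosen to emulate week-0 dispersion: thickness
spreads 0.02/0.09/0.21 mm, MPI spreads 23.9/7.12/10.02; the SR spread is
set to 3 px so that the latent roughness stays positive at the default
amplitude). Treatment effects are standardized paired shifts: at week w
the latent value moves by `effect × spread`. With all effects zero,
week-to-week variation is pure measurement noise (new speckle, roughness
and jitter draws), so paired differences are symmetric about zero and the
Wilcoxon battery is exactly calibrated — this is what the replicated-null
tests check. A latent SLEB thickness ≤ 0 makes the band absent from that
frame, the mechanism behind control-arm SLEB prevalence
(`control_sleb_absent_fraction`, default 0.29) and treated-arm dropout.

AKASI severity scores are scalars, not images: baseline uniform on
[1.2, 8.6] (the plausible clinical range), post-treatment value
`max(0, baseline − N(4.4, 1.2))`, interpolated linearly at intermediate
visits. The defaults were picked once so the default cohort lands in the
clinically reported regime (large rank effect, roughly half the patients
clearing); the AKASI scoring rubric itself is out of scope. Markers map
1:1 to patients in generated cohorts; the analysis keys AKASI on
patient_id, so many-to-one mappings in real data work unchanged.

One master seed drives everything through per-frame substreams; identical
specs give bit-identical images and byte-identical reports.

What the phantom does *not* model — acoustic point-spread correlation of
speckle (real B-mode speckle is spatially correlated; gamma speckle here
is i.i.d. per pixel), depth-dependent attenuation and gain, keratin
shadowing, oblique probe placement, segmentation error (contours are
ground truth by construction) — means passing tests demonstrate the
correctness and calibration of the *pipeline*, not the clinical validity
of any feature on real images. In particular GLCM values on phantoms are
not comparable to GLCM values on device images.

## Statistical design

* **Two-stage testing.** Two-sided test first; one-sided direction test
  only when the two-sided test rejects at α. The directional type-I error
  of the whole procedure therefore equals the two-sided size.
* **Wilcoxon signed-rank.** Zero differences dropped (classical
  convention; Pratt's method is not implemented). Exact null distribution
  for n ≤ 25 without ties, else normal approximation with tie and
  continuity corrections. The z used for effect sizes always comes from
  the (corrected) normal approximation, so r is computed consistently
  whether or not the p-value was exact. Fewer than 5 nonzero pairs is an
  error: the test is refused rather than run underpowered.
* **Effect size.** r = |z|/√n graded small < 0.3 ≤ moderate < 0.5 ≤ large.
  The formula and cuts are the ones that reproduce the published star
  annotations for this battery type; they are a documented convention,
  not a derivation.
* **Mann–Whitney.** Exact for untied samples up to n = 25 per group, else
  tie-corrected normal approximation with continuity; same two-stage
  gate.
* **Kruskal–Wallis + Dunn.** Tie-corrected H; Dunn pairwise z on pooled
  ranks with tie correction, Holm-adjusted by default (configurable,
  including none). Pairwise tables are produced only on omnibus
  rejection. Groups with n < 2 are excluded with a recorded warning; an
  all-constant pooled sample short-circuits to a non-rejection. For two
  groups the Dunn z is algebraically the tie-corrected Mann–Whitney
  normal approximation without continuity correction (tested).
* **Sample size.** Smallest n whose two-sided noncentral-t paired power at
  dz reaches the target, then divided by the Wilcoxon ARE and rounded up:
  min-ARE 0.864 (conservative bound, default) or 3/π (normal-theory). At
  α = 0.05, power 0.9, dz = 0.5 the t-test needs 44 pairs and the min-ARE
  correction gives 51. The degenerate request `power → α⁺` bottoms out at
  n = 2, the smallest size with a defined t statistic.
* **Power verification.** Monte-Carlo rejection fraction of the two-sided
  Wilcoxon (normal-approximation path, appropriate at the n ≈ 51 scale)
  over Normal(dz, 1) paired cohorts; 10,000 reps give a binomial SE of
  ≈ 0.003 around the ≈ 0.93 power at n = 51.
* **Multiplicity.** The longitudinal battery reports raw p-values — the
  convention of the study design it implements — with Holm available but
  off by default in the stage-wise Dunn step only.

## Pipeline rules

Longitudinal analysis is complete-case: markers must have a record at
week 0 and every requested follow-up week (the exclusion count is
logged); within a cell, pairs additionally require the layer to be
present at both visits, so SLEB dropout removes a marker from SLEB cells
only. Exactly one frame per marker per visit is enforced — duplicate
records are an error, not silently aggregated. Cells whose test refuses
(fewer than 5 nonzero pairs, e.g. an identically-zero HEP ratio) are
recorded as skipped rather than fabricated. Reports are assembled with
sorted keys and no timestamps, so a rerun on the same seed is
byte-identical; skipped stages appear as `"skipped"`, never silently
missing.

## Problem sizes used in tests

Replicated-cohort tests (null calibration, parameter recovery) use a
scaled phantom — 112×128 px at 0.04 mm/px, 8–16 markers, two visits, and
a GLCM-free feature subset — chosen to keep hundreds of replicate
cohorts cheap while preserving every mechanism under test; single-frame
and full-pipeline tests use the full default geometry. The
parameter-recovery battery excludes features mechanically coupled to SLEB
pixel count (PAR, ACR, and EPI, whose histogram-entropy estimator is
biased by sample size), because those are genuinely non-null under a
thickness change; this is a property of the features, not of the
implementation.

## Known limitations

* Contours are inputs; no segmentation is provided or validated.
* GLCM parameter choices make cross-study numeric comparison of texture
  values approximate at best.
* The sample-SD roughness estimator conflates waviness and jaggedness;
  detrended roughness metrics are out of scope.
* One frame per marker per visit; multi-frame aggregation is rejected
  explicitly rather than implemented.
* Missed-visit imputation is not implemented; the complete-case rule can
  discard a large fraction of sparse cohorts.
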