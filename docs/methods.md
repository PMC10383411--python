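# Methods

`paddyrisk` re-creates, as a tested pipeline, a precision-agriculture
analysis that links rice lodging severity to the spatial distribution of
soil available nitrogen (SAN) in a paddy field surveyed by a small
unmanned aircraft. This note documents the models, the synthetic field
generator that stands in for the survey data, the numerical choices, and
the limits of what the tests demonstrate.

## Lodging assessment

Plant height is taken from photogrammetric surface models. The canopy
height model is

    CHM = DSM − DTM

with the DTM a bare-soil terrain model and DSM the crop surface at two
dates: the seasonal canopy maximum (height `r`) and harvest (height `y`).
Assuming plant length does not change between the two dates, the height
drop and the stem inclination angle are

    δCHM = r − y
    θ = arcsin(y / r)     (90° upright, 0° flat)

Severity is scored on a six-level scale in 18° steps: level 0 for
θ ∈ (72°, 90°] down to level 4 for θ ∈ (0°, 18°], with level 5 reserved
for θ = 0 exactly (completely lodged). The original field scale is an
ordinal visual score; the interval convention here (half-open intervals,
level 5 only at exactly zero) is one consistent reading of "six levels in
18° increments" and is a package choice, not an agronomic standard.

Numerical guards: negative CHM values are clamped to zero (photogrammetric
noise on bare patches), `y/r` is clipped to [0, 1] before the arcsine, and
pixels with `r < r_min = 0.05 m` are set to nodata — there is no crop whose
angle could be measured. No constant height-bias correction is applied: a
constant underestimate cancels in δCHM and shifts θ by only a few degrees,
small against the 18° class width. Per-cell severity is computed from the
cell-mean θ (not the mean of per-pixel levels), which matches the map-scale
reading of a severity raster.

## Soil nitrogen estimation

Bare-soil reflectance digital numbers (DN) in four bands (green, red,
Red edge, NIR) are averaged over buffer circles (default radius 0.5 m) at
the soil-sampling points. From the four means, 28 candidate predictors are
formed: the 4 single bands, and the 6 pairwise differences, sums, ratios
and normalized difference indices NDI(Rᵢ, Rⱼ) = (Rᵢ − Rⱼ)/(Rᵢ + Rⱼ).
Each is screened by Pearson correlation against the measured chemistry;
the best feature (largest |r|, ties broken by inventory order) enters a
single ordinary least-squares regression

    SAN = a + b · (feature)

The reference relation embedded in the synthetic generator is
SAN = 287.86 − 0.046 × (green − red), in mg N kg⁻¹. AIC is reported with
the Gaussian profile form n·ln(RSS/n) + 2k, k = 2, constants dropped —
only differences between candidate fits are meaningful. The fitted
equation is evaluated per pixel (buffer means enter only the fit) and
compiled onto the 1 m mesh as a fertility map with an 80–200 mg N kg⁻¹
optimum-range flag.

Zone statistics use pixel-centre membership, not area weighting, for both
circles and mesh cells — the behaviour of common GIS zone-statistics
tools, and the contract every zonal function in this package is tested
against with an exhaustive pixel-centre oracle.

## Soil-line classification

Bare-soil red and NIR reflectance fall on a linear locus (the soil line);
pixels contaminated by vegetation residue ("mixels") sit above it with
elevated NIR. Membership of the clean class is modelled by four-band
logistic regression,

    p = 1 / (1 + exp(−(α + Σᵢ βᵢ Xᵢ))),   Xᵢ ∈ {green, red, Red edge, NIR}

fitted by iteratively reweighted least squares on standardized predictors
(all-zero start, tolerance 1e−8 on the step, 100 iterations maximum, ridge
jitter 1e−6 on the weighted normal equations), with coefficients reported
on the original DN scale. Complete separation — the good case when the two
pixel groups are distinct — is detected either by coefficient-norm
divergence or by the deviance vanishing, and reported as a flag with the
achieved boundary rather than treated as failure. When no training labels
are supplied, provisional labels come from an exact 1-D two-means split of
the NIR residuals about a provisional soil line fitted to all pixels; the
logistic model is then refitted on those labels. The soil line itself is
OLS of NIR on red over the clean class, with RMSE reported.

## Risk synthesis

The lodging and fertility mesh tables are inner-joined on cell id. The
SAN–θ relationship is quantified by Pearson correlation and an OLS line of
θ on SAN over *inside* cells only: cells whose centre lies within 4 m of
the field boundary are the headland strip, where the transplanter's
overlapping fertilizer application lodges rice regardless of soil
nitrogen. Edge cells are counted, carry a separate caution flag, and are
never merged into the SAN-based risk flags.

A basal dressing of R kg N ha⁻¹ mixed through a tillage layer of depth d
(m) at bulk density ρ (Mg m⁻³) adds R / (10·d·ρ) mg N kg⁻¹ to the soil;
the reference dressing (70 kg N ha⁻¹, 0.1 m, 1.0 Mg m⁻³) adds exactly
70 mg N kg⁻¹. Absorbable nitrogen is estimated SAN plus this fertilizer
concentration. Cells are flagged `lodging_possible` at SAN ≥ 140 mg N kg⁻¹
(the onset below which the synthetic canopy stays upright, and a
field-observed threshold in the motivating survey) and `above_guideline`
at absorbable N ≥ 200 mg N kg⁻¹. Both thresholds are field-specific
parameters, exposed on the CLI, not estimated quantities: no change-point
procedure is applied.

## The synthetic field generator

No survey data are distributed, so `synthetic_data` generates a complete
field with the statistical structure the analysis assumes. Reference
conditions: a 55 × 80 m rectangle, ~5 cm ground sample distance, SAN
spanning 78–200 mg N kg⁻¹, terrain slope 0.15°, 20 + 15 = 35 soil samples,
70 kg N ha⁻¹ basal dressing.

* **SAN surface** — north→south decreasing linear trend plus
  moving-average-smoothed Gaussian noise (kernel width = correlation
  length, default 12 m), clipped to the range last. The lodging-prone
  high-SAN ground therefore sits on the north side.
* **Bands** — green − red inverts the estimating equation exactly, plus
  band noise (default SD 50 DN). The red band carries SAN-independent
  smooth brightness variation (default SD 300 DN; moisture/texture
  patches). Because green is generated as red + (green − red), this
  brightness variation cancels *exactly* in the green − red difference and
  degrades every other band combination — this is the structural reason
  the green − red index screens best, mirroring the agronomic argument
  that a difference of adjacent bands cancels common brightness. The Red
  edge band interpolates red and NIR and carries its own smooth soil
  variation (SD 400 DN). NIR lies on the soil line
  NIR = 150 + 1.3 · red for clean pixels; a fraction (default 0.2) of
  pixels are mixels with a +700 DN NIR boost, arranged in patches
  (threshold of a smoothed field, 4 m scale) the way tillage residue
  clusters in rows. The DN scale is chosen so the estimating equation's
  printed coefficients are self-consistent: green − red spans
  ≈ [1910, 4562] across the SAN range.
* **Canopy** — maximum canopy height r grows linearly from 0.5 to 0.7 m
  across the SAN range; the inclination response is θ = 90° for SAN ≤ 140
  mg N kg⁻¹, falling linearly to 10° at SAN = 200, with height noise
  SD 0.03 m, and a 4 m edge strip forced to lodge regardless of SAN. This
  response curve is a stand-in with the right sign, onset and severity —
  no quantitative lodging model is claimed for real fields.
* **Samples** — a jittered grid of 35 points; measured SAN = latent SAN
  plus noise (SD 8 mg N kg⁻¹); total C and N are generated with only weak
  correlation to SAN.

All randomness derives from per-component streams spawned from a single
seed, so every artefact is reproducible and the operations can be invoked
in any order.

What the generator does **not** emulate: radiative transfer of soil
reflectance, soil moisture gradients, photogrammetric artefacts with
spatial structure (doming, melt), rolling topography, non-rectangular
fields, or weather-driven lodging. Passing tests therefore demonstrate
that the pipeline's statistics recover the structure they assume, not that
the estimating equation or the thresholds transfer to any real field —
the motivating survey itself reports much weaker correlations (R² ≈ 0.45)
than the synthetic field yields, because real bare-soil reflectance is
dominated by moisture and residue effects the linear model ignores.

## Problem sizes and determinism

Tests run on reduced fields (≈ 12–20 m extent, 0.1 m GSD) with the default
noise levels; the multi-seed statistical checks and the acceptance script
use the full 55 × 80 m reference field at ~5 cm GSD. Soil-line
classification operates on a deterministic 20 000-pixel subsample of the
band stack. The zonal-statistics oracle comparisons run on grids up to
200 × 200. All stochastic tests use fixed seeds; hypothesis-based property
tests are derandomised.

## Known limitations

* GeoTIFF support covers the single-band float32 north-up square-pixel
  profile this pipeline produces and consumes; no CRS reprojection, no
  multi-band rasters, no area-weighted zonal statistics.
* The 1-D two-means initial labelling of the soil-line classifier assumes
  the mixel class is the minority above the line; fields with majority
  residue cover would need user-supplied labels.
* The mesh edge test measures distance from the cell centre to the
  boundary outline, which for non-convex fields flags cells near internal
  notches as edge; that matches the fertilizer-overlap interpretation but
  may surprise users expecting a buffer of the exterior only.
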