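# Methods

## Data model and coordinate conventions

A pullback is an ordered list of segmented frames with an isotropic
in-plane pixel size (mm) and a longitudinal frame pitch (mm; pullback
speed / frame rate, 0.2 mm for a 36 mm/s, 180 fps acquisition). A pixel
at array index (row, col) has its center at (x, y) = (col, row) ×
pixel_size. Ray angles are measured from the +x axis toward +y in
degrees on [0, 360). The origin and direction are arbitrary — only
angular extents enter the feature set — but fixed and tested (rotating
a mask by 90° rolls the ray profile by 90 indices).

Labels are mutually exclusive integers: 0 background, 1 lumen,
2 calcium, 3 lipid, 4 fibrous cap. The lesion is the stented frame
span supplied in metadata; there is no automatic lesion detection.

## Ray casting

From the lumen center of mass, `n_rays` (default 360) rays are walked
outward with nearest-neighbour label sampling at a step of
pixel_size / 2. The lumen boundary is the first lumen→non-lumen
transition, placed sub-pixel at the midpoint of the straddling sample
pair (maximum quantization error one quarter pixel plus rasterization
error). Fibrous-cap thickness on a ray is the total radial extent of
cap samples (count × step), which is robust to the cap being split by
interleaved labels. Calcium entry/exit radii are the first/last
calcium samples, each pushed half a step outward/inward; the entry
radius is floored at the lumen radius so depth is never negative.

Thickness is measured radially along the ray, not normal to the cap
surface. For near-circumferential caps the two coincide; for very
oblique caps the radial measure overestimates true (normal) thickness
by 1/cos of the obliquity. Centroid-ray geometry supports only the
radial measure, and the same convention is used by the analytic truth
generator, so validation is internally consistent.

A lumen whose center of mass falls outside the label (non-star-shaped)
triggers a warning; rays are still measured from the centroid and the
boundary is taken after the first lumen run encountered. Frames with
no lumen at all are skipped for plaque statistics (with a warning) but
still count toward lesion length, which is defined by the lesion span.

## Feature definitions

Per frame: lumen area is the lumen pixel count × pixel area (a raster
quantity, not a ray quantity); diameters are centroid chords
r(θ) + r(θ+180°), minimized/averaged over ray pairs; circumference is
Σ r Δθ. Calcium per-ray thickness is exit − entry radius and depth is
entry − lumen radius; the frame stores the per-ray extrema. Angular
extents are (number of covered rays) × (360/n_rays); disjoint arcs sum.

Fibrous-cap thickness classes: 1: T ≤ 65 µm, 2: 65 µm < T < 150 µm,
3: T ≥ 150 µm, T: all. The 65 µm boundary goes to class 1 and 150 µm
to class 3, per the inclusive inequalities; 65 µm is the conventional
thin-cap fibroatheroma cutoff. Per-class cap cross-sectional area is
obtained by assigning every cap pixel to the class of its (circularly)
nearest cap-bearing ray, so the class areas partition the total
exactly.

Per lesion: lesion length = span frames × pitch. Max/min calcium
thickness (and depth) are the max over frames of the per-frame maximum
and the min over frames of the per-frame minimum; frames without the
tissue are skipped, so a single calcium frame defines both extrema.
"Maximum FC area-T" is the max over frames of the total cap area (not
the sum of per-class frame maxima, which can occur on different
frames). FC surface area per class sums covered arc length × pitch
over frames, with the total defined as the sum of the three classes so
conservation holds to the last bit. FC burden is surface area as a
percent of total lumen surface area (Σ circumference × pitch) and
therefore lies in [0, 100]. Published lesion-level burden values exist
that greatly exceed 100 under an evidently different, unstated
normalization; this package follows the literal covered-fraction
definition and documents the discrepancy rather than guessing the
alternative.

Vulnerable-plaque flags (microchannel, macrophage infiltration,
cholesterol crystal, layered plaque, calcium nodule) are any-frame
presence over the lesion.

## Statistical cascade

1. **Group comparison** — two-sample pooled-variance t-test for
   continuous features (Welch behind a flag), Pearson chi-square
   without continuity correction for the binary flags. Missing values
   drop per feature; zero-variance features report a missing p with a
   warning (identical constant groups report p = 1).
2. **Redundancy pruning** — pairwise Spearman |ρ| over all features;
   average-linkage hierarchical clustering on 1 − |ρ| orders the
   heatmap. Within each connected group of features pairwise-linked at
   |ρ| > 0.9 the member with the smallest univariate p is kept, ties
   broken by canonical feature order. Among near-duplicate features
   the winner is decided by noise; the cluster, not the member, is the
   identifiable unit.
3. **Logistic regression** — single-predictor maximum-likelihood fits
   per feature (OR = e^β, Wald 95% CI); features with univariate
   p < 0.05 enter a joint fit. Complete separation is flagged (not
   raised) with an infinite-bound CI; no Firth or penalized correction
   is applied, matching plain-MLE practice in the emulated analyses.
   An events-per-variable ratio < 10 warns. Rank-deficient designs
   raise an error naming the collinear columns.
4. **ROC** — empirical AUC in the Mann–Whitney rank formulation (ties
   counted half), 95% CI by stratified bootstrap (resampling cases and
   controls separately; 2000 replicates by default, seeded), optimal
   cutoff the observed threshold maximizing sensitivity + specificity
   for the rule score ≥ cutoff, smallest threshold on ties (favouring
   sensitivity). The scan is vectorized with sorted-array bisection so
   it stays exact and fast at 10⁵-scale inputs.

All stages run under one seeded configuration; reports serialize to
JSON with sorted keys, so identical inputs give byte-identical files.

## Synthetic data

**Phantoms.** A `LesionSpec` gives the lumen radius as a constant or a
function of (θ, z), plus cap arcs (span and thickness, possibly
θ-dependent) and calcium arcs (span, thickness, depth). Analytic truth
uses 0.01° quadrature: lumen area ∫½r²dθ, circumference ∫r dθ, class
membership resolved pointwise (for a linear thickness ramp this
reproduces the interval-inversion class fractions to 10⁻³).
Rasterization assigns each pixel the label of the shell containing its
center and auto-sizes the image to the outermost tissue radius plus a
0.1 mm margin; a supplied shape too small to contain the vessel is an
error, as is a pixel size above 20 µm (a 65 µm class boundary needs
several samples per cap). Eccentric lumens (circle offset from the
image center) exercise centroid ≠ image-center geometry.

**Cohorts.** A latent severity s ~ N(0,1) drives FC surface area-T as
exp(0.5 + 1.2·s) — log-normal parameters chosen so the marginal mean
(≈3.3 mm²) and SD (≈5.7 mm²) match cohort-scale lesion statistics,
giving the strong right skew seen in practice. Class surface areas
split the total by a concentrated Dirichlet (α = (5, 50, 35)), making
per-class features correlate at |ρ| > 0.9 with the total — the
redundancy structure the pruning stage exists to remove. Plaque-burden
features (cap angle, max cap area, calcium angle/thickness, lesion
length) couple to s at latent correlation ρ_nuis (default 0.7);
vulnerable-plaque flags threshold correlated latents at realistic
prevalences (0.11–0.68). Lumen area/diameter and minimum cap
thickness are generated independent of outcome as null features
(diameters are exact monotone transforms of areas, another pruning
target). The outcome is Bernoulli(expit(β₀ + β·z)) on within-cohort
standardized FC surface area, with β = ln 2.38 per SD by default and
β₀ calibrated by root-finding so the expected event fraction is 0.231
(104 patients by default). The full generative truth — including the
calibrated intercept and the standardization basis — is returned with
the table.

What the generator does not emulate: real OCT texture or segmentation
error (masks are exact), inter-feature structure beyond a single
severity latent, censoring or follow-up time (the outcome is a binary
endpoint), and any direct dependence of the outcome on features other
than FC surface area. Passing tests therefore demonstrate correctness
of the measurement and inference machinery, not clinical validity.

## Identifiability at cohort scale

With ~104 lesions and ~24 events, an OR of 2.38 per SD yields a
marginal AUC of ≈0.68 for FC surface area, and the multivariate stage
(entering every univariate-significant feature, often 4–7 correlated
ones) frequently declares nothing significant or crowns an arbitrary
member of the cap-burden cluster. This is a property of the design,
not a defect: at this scale only the cluster-level signal is
identifiable. Tests of signal recovery therefore run at n = 800–2000,
where coverage and family-level attribution are stable. Relatedly,
because ~20 pruned features are each tested at α = 0.05 with no
multiplicity correction (deliberately, matching the emulated
workflow), a permuted-outcome cohort still yields at least one
multivariate "significant" feature in roughly a quarter of runs — the
expected family-wise error of an uncorrected cascade, worth keeping in
mind when reading single-cohort feature-screening studies.

## Numerical choices and tolerances

- Phantom recovery tolerances: 3% on surface areas, 2° on angles,
  2 pixels on calcium thickness/depth, 1 burden point — the observed
  raster error at 10 µm pixels plus margin; errors shrink with pixel
  size (asserted as strict improvement from 20 µm to 10 µm).
- Ray count 360 (1° sampling) balances angular resolution against the
  pixel footprint at typical radii; it must be even so diameters can
  pair opposed rays.
- Logistic fits: maxiter 200; |β| > 15 or a non-finite standard error
  is treated as separation.
- Bootstrap and simulation sizes in tests (200–2000 replicates,
  cohorts of 104–5000) are chosen so every stochastic assertion sits
  several standard errors from its threshold at the frozen seeds.

## Limitations

- Radial (not normal) cap thickness; see above.
- Non-star-shaped lumens are measured best-effort from the centroid.
- The contingency chi-square and pooled t-test are the defaults of the
  emulated workflow, not recommendations; Welch and exact tests may be
  preferable for small or unbalanced groups.
- DICOM ingestion, raw OCT reconstruction, automatic segmentation and
  survival modelling are out of scope.
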