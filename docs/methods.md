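# Methods

This note documents the models, numerical choices and limitations behind
`canopyphene`. It covers what the synthetic generators emulate, the exact
conventions of each processing stage, and the open design choices the package
resolved.

## Synthetic trial model

The trial generator produces a balanced split-plot layout: every genotype ×
treatment × block cell occurs exactly once (default 10 genotypes, FI/RI, 6
blocks → 120 plots). Yield per plot is

```
Y = (mu_FI + g_genotype + b_block) × f_treatment + ε,   ε ~ N(0, σ²)
```

with a multiplicative per-genotype treatment factor (1 under FI) and additive
genotype/block effects. Defaults encode the study conditions the pipeline
targets: `mu_FI = 3.24` t ha⁻¹ and RI factor `0.756`, so the noiseless RI mean
is 2.45 t ha⁻¹ and the drought intensity index 0.76; residual SD defaults to
0.3 t ha⁻¹, a plot-to-plot coefficient of variation of ~9–12% that is typical
of small-plot yield trials (the trial's own within-cell spread is not
published, so this is a package choice). The multiplicative-treatment /
additive-genotype form matches the assumptions of the balanced fixed-effects
ANOVA used downstream, which keeps recovery tests well-posed.

Seed metrics: per-genotype 1000-seed weights (default 2.6–3.3 g spread, RI
factor 0.93) and sieve-caliber proportions over 1.7/1.4/1.18 mm meshes drawn
from a Dirichlet whose mean shifts mass from the 1.7 mm fraction to the smaller
sieves under RI — reproducing the qualitative seed-size response to water
deficit. Proportions sum to one by construction. All generators are
bit-identical under a fixed seed (`numpy.random.default_rng`).

## Synthetic scenes

**Hyperspectral.** Vegetation reflectance is a parametric Gaussian-feature
template, not a radiative-transfer model: a 0.10 visible baseline with a green
peak (555 nm), blue/red chlorophyll absorption dips whose depth scales with
`chlorophyll_level`, a sigmoid red edge at 715 nm to a 0.48 NIR plateau, and a
970 nm water depression of depth 0.18·(1 − `water_level`). This gives the
index-relevant features (green peak, red edge, water dip) their correct
qualitative behaviour — e.g. WBI = R900/R970 strictly increases as water level
drops — without claiming physical accuracy. Soil is a featureless linear ramp
(NDVI < 0.3 everywhere); shadow pixels are 0.25× copies of their underlying
material spectrum; the reference tile is flat at 0.95. Raw digital numbers
follow `DN = dark + (white − dark)·R + noise`, with a broad illumination curve
in the white spectrum; calibration is therefore the exact inverse of the
generative model, and round-trips are machine-precision at zero noise.
Optional foil pixels match the tile in brightness but carry heavy per-band
noise, exercising the tile/foil discrimination.

What the scenes do **not** emulate: mixed pixels at material boundaries,
BRDF/illumination geometry, sensor striping or smile, within-canopy spectral
variability, specular highlights and inflorescences. Passing segmentation and
index tests therefore demonstrates correctness of the computations, not
robustness to those field artefacts.

**Thermal.** Object temperatures (leaf raster, soil, dry-reference leaf) are
pushed through the fourth-power graybody forward model
`T_app⁴ = ε·T_obj⁴ + (1−ε)·T_refl⁴` (kelvin); foil pixels read the reflected
temperature directly, as a fully reflective target does at emissivity-1
conversion. With `dew=True` leaf temperatures sit at `T_air − wet_depression`
(default 4 K), defining the wet-reference regime. Atmospheric transmission,
distance effects and sensor-specific Planck calibration are deliberately
ignored: the fourth-power form is standard, closed-form invertible, and
consistent between generator and correction, which is what the round-trip
contract (identity to 1e-9 K) requires. The within-plot spatial variance of
leaf temperature (0.15 K default) is likewise a package choice; it is not a
published quantity.

## Processing conventions

- **White-tile selection**: candidate pixels above the `dn_quantile`
  brightness quantile (default 0.99 for 512×512 scenes; scale it with scene
  area) are grouped by 8-connectivity; a component qualifies if (a) its median
  per-pixel spectral coefficient of variation, measured on the ratio to the
  component mean spectrum, is below 0.05 — crumpled foil fails this — and
  (b) its mean DN is at least 2× the scene median, so a tile-less scene
  errors out instead of promoting the brightest ordinary material. The
  largest qualifying component wins.
- **Calibration**: per band, `(DN − dark)/(white − dark)`; any band with
  `white ≤ dark` is an error naming the wavelength. Jointly scaling DN, white
  and dark leaves reflectance unchanged (affine invariance).
- **Segmentation**: pixel kept iff NDVI > 0.4 AND R(838 nm) > 0.15 AND
  R(554 nm) > 0.04. The threshold *values* are package defaults (the
  procedure's thresholds are not published); they are config-exposed and
  recorded in the mask provenance. Raising any threshold never adds pixels.
- **Smoothing**: Savitzky–Golay, order 3, window 11 bands, per pixel along the
  band axis; edges use the terminal-window polynomial fits
  (scipy `mode="interp"`), i.e. polynomial extrapolation within the first and
  last half-windows.
- **Vegetation indices**: published wavelengths resolve to the nearest
  instrument band within 5 nm (a 204-band 400–1000 nm grid has no exact
  integer wavelengths). The plot-level value is the mean over canopy-mask
  pixels of the per-pixel index, computed on smoothed reflectance. The
  catalog is data: 41 entries, each with its formula source; where the
  original trial's supplementary wavelength table was not available, the
  index's canonical publication wavelengths are used (and WCI, whose cited
  formula could not be recovered, is a documented catalog default using green,
  red and NIR bands). Normalising transforms (log for the simple-ratio
  chlorophyll family, sqrt for MCARI, reciprocal for WCI) are recorded in the
  catalog but applied only in the statistics layer, never to stored values.
- **Band grouping**: scanning bands in wavelength order, a new group starts
  when Pearson correlation with the current group's *seed* (first) band drops
  below r = 0.8; the representative is the group's central band — the
  published procedure fixes only "one wavelength per group", so centrality is
  the package's choice, config-exposed. A zero-variance band joins the current
  group with a warning. The NIR average (≥ 760 nm) is appended as a
  pseudo-band.

## Tolerance indices

DII is the ratio of treatment means Ȳs/Ȳp — the only reading consistent with
the published numbers (2.45/3.24 → 0.76, and a reference cultivar ratio of
0.93 giving its DTI = 1.23). YTI uses the stress-tolerance-index form
(Yp·Ys)/Ȳp², which reproduces the published discrimination between lines that
tolerate drought per se (high DTI, modest YTI) and lines that simply yield a
lot (high YTI). All indices are invariant to a global rescaling of yields, and
DTI-R = DTI·DII/DII_R holds exactly. Report rounding is two decimals half-up.

## Statistics

The published mixed model `trait ~ treatment × genotype + (1|block)` is
implemented as a fixed additive block term in a balanced fixed-effects ANOVA
(statsmodels OLS + anova table): with a complete balanced design the F-tests
for treatment, genotype and their interaction coincide with the REML fit and
estimated marginal means equal cell means, so iterative variance-component
fitting is avoided; unbalanced input falls back to type-III sums of squares
with a warning. Generalized eta squared follows the Olejnik–Algina scheme —
η²_G = SS_effect/(δ·SS_effect + Σ SS_measured + SS_error) — reducing to
SS/(SS + SS_resid) when all factors are manipulated.

Standardized pairwise contrasts use d = Δ(cell means)/√MS_resid; the
root-residual-mean-square standardiser is a package decision (the published
"standard deviation of the population" is not defined further), and a raw
pooled SD can be supplied instead. The consistency filter keeps a contrast iff
|d| exceeds the threshold (default 1 SD) in *every* repetition. Correlation
method choice is operationalised as Shapiro–Wilk at α = 0.05 on both margins
(Pearson iff both pass); displayed significance is raw p < 0.05 with no
multiplicity correction, matching the reference analysis (a
Benjamini–Hochberg option would be a one-line addition but defaults matter
here). PCA standardises columns (population SD) and reports variance
fractions that sum to one; clustering is agglomerative with average linkage on
Euclidean distances (linkage unstated in the reference; average is the cited
routine's default), cut at k = 5.

IQR outliers use linear-interpolation quartiles and the 1.5·IQR fence within
genotype × treatment groups; groups smaller than 4 are skipped with a warning.

## Problem sizes and determinism

The test suite and the orchestrated `run-all` use 32–64 px scenes with the
full 204-band axis and the 120-plot default trial; stochastic recovery
properties (ANOVA type-I error ≈ 0.05, power at the configured FI/RI
separation, 1.5-SD contrast recovery within ±0.2, correlation false-positive
rate) are measured over 200 fixed-seed replicates — sizes chosen so the whole
suite runs in well under a minute while the Monte-Carlo error stays inside
each property's stated band. Every random draw flows from an explicit seed;
identical seeds give bit-identical tables, cubes and rasters.

## Known limitations

- The graybody model shares its functional form between generator and
  correction; it validates the inversion, not the camera physics.
- Synthetic scenes cannot certify robustness to mixed pixels, illumination
  drift or real foliage variability (see above).
- The 41-index catalog's wavelength assignments follow each index's original
  publication, not the unpublished supplementary table of the reference
  trial; per-index values on real cubes may differ where that table deviated.
- Field-acquired quantities (per-genotype TI1 tables, seed-weight rankings,
  VI effect-size orderings, trait-correlation R² values) depend on the
  original imagery and are out of reach by construction; the package
  guarantees their report *structures* and the correctness of every
  computation that would fill them.
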