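# Methods

`stainslice` implements a grey-level intensity-slicing analysis of pan
cytokeratin immunohistochemistry (IHC): tumour sections are segmented into
narrow grey-level ranges, each range is profiled by 33 computational
morphology features, features are averaged per patient, and their
prognostic value against a binary distant-metastasis endpoint is evaluated
by ROC analysis with internal validation.  Because no patient image set is
distributed with the package, a synthetic tumour-nest generator provides a
ground-truth test bed for every stage.

Grey convention, fixed project-wide: **0 = black = maximal stain uptake,
255 = white = no stain**.  Lower grey value therefore always means stronger
staining.

## Grey-level slicing

An intensity range `lo`–`hi` is extracted by whitening every pixel outside
it (set to 255), reproducing a two-step thresholding macro: whiten
`v <= lo`, then whiten `v >= hi`.  Consequently **both** shared boundary
levels are excluded from adjacent ranges; the only exception is `lo = 0`,
where level 0 is kept because only the upper command applies.  The prose
labels of such ranges ("160–180") read as inclusive, and an
`inclusive-lower` boundary mode (`lo <= v < hi`) is available, but the
macro semantics are the default because they are the only executable
statement of the procedure.  Level 255 never counts as kept, and fill
pixels are indistinguishable from native white in the sliced raster, so
the boolean `kept_mask` is carried alongside every slice as the
authoritative record.

The default range set is the seven narrow ranges
0–130, 130–160, 160–180, 180–200, 200–220, 220–240, 240–255 (the two
darkest are wider because intense staining is rare), plus the original
0–255 image and the specific/non-specific split at the 220 grey level
(0–220 covers epithelial tumour nests; 220–255 is stromal background).
With the default set, kept sets are pairwise disjoint and their union is
"every pixel except the six shared boundary levels and white": on an image
holding one pixel per level, 249 of 256 pixels are kept.

## Feature families (33 features per image × range)

GLCM and fractal features are computed on the white-filled sliced image —
the fill pixels take part, so these features describe the spatial
arrangement of the kept pattern against its background.  First-order
statistics are computed strictly on kept pixels.

**GLCM (5).**  Co-occurrence matrix over the full 256 grey levels,
distance 1, angle 0°, symmetric, normalised; features ASM = Σp²,
contrast = Σ(i−j)²p, correlation = Σ(i−μx)(j−μy)p/(σxσy),
IDM = Σp/(1+(i−j)²), entropy = −Σp ln p (natural log).  Offset, angle,
symmetry and quantisation are config-exposed since texture-plugin defaults
vary; the values above are the package defaults.  Correlation is reported
as NaN (flagged) when a marginal is degenerate, e.g. on a constant or
all-white image.

**Monofractal (23).**  Greyscale box counting over a linear box-size
series (default 5–575 px step 3; 191 sizes) with grids repositioned 12
times: the reference grid at offset (0,0) plus 11 seeded pseudo-random
offsets in `[0, eps_min)²`.  Per box of edge `eps`:

* differential (Sarkar–Chaudhuri) count
  `n_b = floor(I_max/h) − floor(I_min/h) + 1`, grey-box height
  `h = eps·256/min(W,H)`; `N(eps) = Σ n_b` and `D_B` is the OLS slope of
  `log N` vs `log(1/eps)`;
* mass `m_b = Σ(255 − v)` (inverted intensity, so stain-dense boxes are
  heavy); `D_M` is the slope of `log μ(eps)` vs `log eps` for the mean box
  mass μ;
* lacunarity `λ(eps,g) = (σ(eps,g)/μ(eps,g))²` from the box-mass mean and
  (population) SD.

The 23 features are, per family: the across-grid mean, SD (sample,
across the 12 grids), min, max, the slope of the grid with highest r², and
the slope standard error and intercept of the grid-averaged regression for
`D_B` (7) and `D_M` (7); slope/SE/intercept of the "optimal cover"
regression on the per-size **minimum** count across grids for `D_X` (3);
and Λ (mean λ over sizes at the reference grid), Λ′ (mean over sizes and
grids), min/max of per-grid means, and the coefficients of variation of
per-grid Λ and of all per-(size, grid) λ values (6).  SD-type and SE-type
features are deliberately distinct quantities: dispersion across grid
positions versus regression slope uncertainty.  `D_X` as "minimum cover
across grids" and Λ as "reference-grid lacunarity" are declared package
conventions — the feature names admit several readings and both are
config-independent, deterministic definitions.

Two numerical safeguards keep the log–log regressions honest on finite
rasters.  Only complete boxes are tiled and box sizes are capped at 45 %
of the short image side (the conventional maximum of box-counting tools):
boxes comparable to the image quantise the count so coarsely that they
bias the slope by up to +0.27 (measured on constant images).  Counts are
edge-corrected by the factor (image area)/(tiled area), which extrapolates
truncated tilings to the full frame; with this convention a constant image
gives exactly D = 2 and zero lacunarity.  The cap drops the largest
entries of the default series on small images (logged); regressions
require at least 3 usable sizes.

Differential counting measures the dimension of the intensity *surface*.
For a binary 0/255 image that surface is a plateau-and-cliff structure
whose dimension approaches (boundary dimension + 1) — about 2.85 for a
level-6 Sierpinski carpet — whereas the *set* dimension log 8/log 3 ≈ 1.893
is what classic box counting estimates.  `counting="binary"` (a box counts
1 when it holds any non-white pixel) is therefore provided and is the
appropriate estimator for binary masks and binary fixtures; greyscale IHC
analysis uses the differential default.

**First-order (5 + auxiliary mean).**  Area (pixels; also µm² when the
pixel size is known), skewness, kurtosis, integrated density
(mean × area) and raw integrated density (Σ of kept values), computed on
kept pixels only.  Moments are population (biased) estimators and kurtosis
uses the excess convention (Gaussian → 0), matching common
image-measurement tools; sample-corrected variants are config-exposed.
Skewness/kurtosis are NaN when the kept set has zero spread or fewer than
4 pixels; an empty kept set yields area 0 and NaN moments rather than an
exception.

Undefined values propagate as NaN everywhere — never as silent zeros,
which would bias downstream AUCs — and are excluded pairwise from
per-patient means (exclusion counts are logged).

## Prognostic evaluation

Per feature × range, patient-averaged values are scored against the
endpoint by the Mann–Whitney AUC (half credit for ties), with DeLong
standard error, Wald 95 % CI and a two-sided p-value against 0.5.  AUCs
below 0.5 indicate association with the opposite class, so range-level
averages use the *folded* AUC `max(a, 1−a)`.  A range's summary is the
mean folded AUC over its features plus, per feature family, the sum of
significant improvements `max(0, |AUC_range − 0.5| − |AUC_original − 0.5|)`
counted only for features with p ≤ 0.05 in that range.  No family-wise
multiple-testing correction is applied (the feature-count context is
reported instead); improvements clip at zero.

**Bootstrap internal validation** (default 1000 patient-level resamples):
for a univariate score the data-driven, hence optimistic, component is the
choice of direction; each resample re-chooses the direction, its folded
AUC is compared with that direction applied to the original sample, and
the mean difference (optimism) is subtracted from the apparent folded AUC.
Degenerate single-class resamples are redrawn and counted.  The CI is the
percentile interval of folded resample AUCs.

**Optimal cutoff**: exhaustive chi-square maximisation (2×2 Pearson, no
continuity correction) over midpoints of consecutive unique scores
restricted to the 10th–90th percentile window — the published principle of
the X-tile cutpoint selector, whose exact internals (its corrected p) are
not reproduced; a min-p correction could be layered on but is off by
default.  Ties resolve to the smaller cutoff; the high-risk side is
reported.  Redundancy between dichotomised classifiers is screened by
Spearman rank correlation.

**Stepwise logistic regression** on continuous values: forward selection
by likelihood-ratio p (entry p ≤ 0.05) with backward elimination
(remain p ≤ 0.05); retained terms report coefficient, HR = exp(β), Wald
95 % CI and drop-one LR p.  Candidates are pre-filtered to univariately
significant features plus clinicopathological covariates.  Perfectly
separating or non-identified candidates (|β| > 10³ or singular fits) are
excluded with a warning rather than poisoning the model.

**ROC sample size.**  The minimal design for testing AUC = 0.5 against an
alternative AUC is solved iteratively from the Hanley–McNeil variance
`V(θ) = [θ(1−θ) + (n₊−1)(Q₁−θ²) + (n₋−1)(Q₂−θ²)]/(n₊n₋)`,
`Q₁ = θ/(2−θ)`, `Q₂ = 2θ²/(1+θ)`, requiring
`z_{α/2}√V₀ + z_β√V₁ ≤ θ − 0.5`.  Defaults follow the convention of the
clinical calculators in common use: two-sided α, equal allocation, and
both variance terms evaluated at the alternative AUC.  With α = 0.05 and
power 0.80, detecting AUC 0.67 needs 40 + 40 = 80 patients (16 expected
positives at a 20 % prevalence).  The alternatives are config-exposed:
evaluating V₀ under the null gives 88, and a 4:1 negative:positive
allocation gives 145 — under that allocation 16 positives can never reach
80 % power at AUC 0.67, whatever the number of negatives, because the
per-positive variance floor `(Q₂−θ²)/16` already exceeds the budget.  The
defaults were chosen because they are the unique standard convention that
is internally consistent with an 80-patient, 16-positive design.

## Synthetic data generator

The generator emulates the structure the assay produces, not its optics:
dark epithelial tumour nests — unions of randomly placed, randomly
oriented ellipses that merge on overlap — on a light stroma background.
Nest pixel values are drawn from a weighted mixture of the five specific
ranges (weights 6:9:10:8:8) and stroma pixels from the two non-specific
ranges (29:30); values are sampled uniformly within a range's kept levels,
two levels inside the boundaries so that the additive Gaussian noise
(default SD 1.5 grey levels, clipped to [0, 255]; clipping above 1 % of
pixels is logged) rarely crosses a range boundary.  The default nest count
(46 at 256², mean radius 16 ± 4 px) was calibrated once so that the
seven-range pixel shares average 6/9/10/8/8/29/30 % (±3 pp over 20
images), i.e. nests cover ≈41 % of the frame.  Nest size/shape
distributions are otherwise free parameters — no quantitative morphometry
was available to fit them — and overlapping nests merge, so the number of
connected dark regions is at most, not exactly, the nest count.

Cohorts attach outcomes by a binormal construction: with prevalence π
(deterministically rounded positives by default, e.g. exactly 20 of 102),
the latent effect feature — per-patient nest area fraction (mean 0.41,
between-patient SD 0.07), or alternatively a noise-heterogeneity latent —
is shifted between classes by `δ = √2·Φ⁻¹(AUC)` standard deviations, which
makes its population AUC analytic.  Positives get the *lower* staining
area, matching the direction reported for this assay.  The latent maps to
the generator through the Poisson-union coverage approximation
`coverage = 1 − exp(−n·Ā/WH)` with a border-clipping correction to the
mean ellipse area (factor 0.889, calibrated once).  Tumour size is
simulated with its own mild signal (AUC 0.65); age and ER status are
outcome-neutral.

What passing tests do and do not show: the generator reproduces the
*pixel-intensity composition* and the nest-on-stroma geometry of the
assay, so it validates the slicing arithmetic, the feature definitions and
the recovery of a designed effect through the full pipeline.  It does not
render cells, chromogen optics, scanner noise, staining batch effects or
spatially correlated biology, so pipeline performance on it says nothing
about the prognostic value of any feature on real sections.

## Problem sizes and reproducibility

Simulation-based checks run at reduced scale chosen to keep the full suite
fast on one CPU: recovery cohorts use 200 patients × 5 images of 64×64 px
(nest radius 6 ± 1.5) with 4 fractal grid positions; the analysis scripts
use the 102-patient cohort shape at the same frame size.  At 64 px the
usable box-size series is 5–28 px; all analytic fixtures (constant images,
the 729×729 level-6 carpet) run with the full 12-grid default.  Stochastic
assertions (null corrected AUC, empty null stepwise model, calibration
bands) are seed-fixed; every generator, grid scan and bootstrap consumes
an explicit seed and identical seeds give bit-identical images, features
and CSV outputs.

## Known limitations

* The macro boundary semantics discard the six shared boundary levels from
  all ranges; with `inclusive-lower` mode the partition is exhaustive
  instead.  Results are insensitive on realistic images (few pixels sit
  exactly on a boundary) but the default is the literal macro.
* Differential box counting on near-binary slices mixes set and surface
  scaling; dimensions of heavily whitened slices should be compared only
  within a fixed range, not across ranges with very different fill
  fractions.
* The stepwise procedure inherits the instability of stepwise selection at
  small n; it reports, but does not correct for, the number of candidate
  features.
* Stain separation is a standard optical-density deconvolution with
  configurable vectors (hematoxylin-like and DAB-like defaults); vectors
  of the original acquisition are not known, so decomposed channels are
  comparable within a run, not across instruments.
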