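# Methods

## Problem and scope

Signet ring cell carcinoma (SRCC) is quantified on digitized H&E sections
by segmenting every tumour cell and its nucleus and reducing each cell to
four inherent properties: cell cross-sectional area **SC** (pixel count of
the cell instance mask), nucleus area **SN** (pixel count of the nucleus
mask), ellipticity **EP** (aspect ratio of the minimum-area rotated
bounding rectangle of the cell mask, short/long ∈ (0, 1]), and
nuclear/cytoplasmic ratio **NCR = SN / SC**.  Per slide, the mean of each
property summarises typical morphology and its standard deviation across
cells quantifies *atypia* (morphological heterogeneity).  Slide-level
summaries joined to clinical covariates feed a standard statistical
battery; detection quality of a cell detector is scored with the FROC
metric.  `ringmorph` implements everything downstream of segmentation —
the masks themselves may come from any instance- or 4-class semantic
segmentation model — plus a synthetic scene generator that provides exact
ground truth for validation.

Areas stay in pixels throughout (a ×40 scan at 0.238 µm/pixel is the
reference scale; µm² conversion is a reporting option only), because every
downstream statistic is either a ratio or compared within one cohort
scanned at a single magnification.

## Morphometry

**Minimum-area rotated rectangle.**  Computed on the *pixel centers* of an
instance: convex hull (`scipy.spatial.ConvexHull`) followed by rotating
calipers — the minimum-area enclosing rectangle of a point set has a side
collinear with a hull edge, so scanning hull-edge directions is exact.
The optimisation minimises the raw product of directional extents;
reported side lengths then add one pixel per side so that an axis-aligned
`r × c` pixel block measures exactly `(max(r,c), min(r,c))` — a
±0.5-pixel footprint convention that is immaterial for the ratio-valued
quantities but keeps areas intuitive.  Degenerate instances (single pixel,
collinear pixels) report a short side of 1 px.  Tests cross-check the
result against a 0.1°-grid brute-force angle sweep (an upper bound on the
optimum) and against `shapely.minimum_rotated_rectangle`.

**EP conditioning limit.**  For near-circular objects the enclosing-rect
area is an almost flat function of orientation: to second order,
`A(φ) ≈ 4ab·(1 + φ²(a² − b²)²/(2a²b²))`.  Rasterization perturbs each
directional extent by up to ~1 px, and when `b/a → 1` that noise
outweighs the curvature of `A(φ)`, so the arg-min orientation — and hence
the measured aspect — becomes ill-determined, with a one-sided bias of
EP toward 1.  Empirically EP recovers the generative `b/a` of rasterized
ellipses (semi-axes ≥ 10 px) to ≤ ~0.04 when `b/a ≤ 0.5`, but can deviate
by 0.1–0.2 for `b/a` in ~(0.75, 0.9).  This is a property of the
minimum-area-rectangle estimator itself (an independent implementation
returns the identical rectangle), not of the calipers search, which
matches the brute-force sweep to < 10⁻⁶ relative area on every tested
instance.  Interpret EP differences between near-circular populations
with this floor in mind; area-based quantities are unaffected (pixel
counts recover π·a·b to < 2% at these sizes).

**Nucleus assignment.**  Each cell receives the nucleus instance with the
largest pixel intersection, computed on the raw label images without
dilation; ties break to the smallest nucleus id.  The rule is applied per
cell, so one nucleus may serve several cells; cells with no intersecting
nucleus keep null SN/NCR and still contribute to SC/EP statistics (counts
of such cells are logged).

**Semantic masks.**  A background/cell/nuclei/boundary mask is converted
to instances by 8-connected labelling of cell ∪ nuclei pixels with the
boundary class removed (the boundary is what separates touching cells);
boundary pixels are then re-attributed to the geodesically nearest
instance by iterative 8-neighbour flooding (ties to the smallest label),
so areas are not biased downward.  Reassignment is configurable off; how
the original pipeline treated boundary pixels is not documented, so this
default is a stated choice of this package.

## Slide aggregation

Means are arithmetic; SDs are sample SDs (n−1) — at the ≥ 500 cells per
slide the inclusion rule demands, the distinction from population SD is
negligible, and the flavour is recorded in output metadata.  SN/NCR
statistics run over nucleus-assigned cells only.  Slides enter cohort
analyses when they carry at least `min_cells` (default 500) segmented
cells.  Aggregation is per slide by default; a grouping key allows
pooling multiple sections of one case.

## Cohort statistics

Two-group comparisons use the Welch t-test by default (slide-level
variances differ between groups in practice; pooled is available) and the
exact/asymptotic Mann–Whitney U as scipy selects.  Multi-group
comparisons use tie-corrected Kruskal–Wallis with Tukey-HSD pairwise
post-hocs on request.  No further multiplicity correction is applied by
default (a Benjamini–Hochberg option exists), matching common reporting
practice for this kind of cohort table.

Continuous markers are dichotomized at the cutoff maximising Youden's
J = sensitivity + specificity − 1 under the rule "positive if value ≥
cutoff".  Candidate cutoffs are the midpoints between consecutive
distinct values *plus* the all-positive cutoff (the minimum value): with
midpoints alone J can be negative on adversarial inputs (e.g. a marker
anti-correlated with the outcome), whereas the all-positive candidate
guarantees J ≥ 0.  Ties resolve to the smallest cutoff.  Cutoffs are
derived in-sample by default, as cutoff-based forest plots usually are;
an optional split is available and in-sample optimism should be kept in
mind when reading the tables.

Effect sizes on a binary outcome come from maximum-likelihood binary
logistic regression.  The forest table labels them `hr` for continuity
with clinical reports that print "HR", but the quantity is an odds
ratio, `exp(β)`, with Wald 95% CIs `exp(β ± 1.96·SE)`; no survival model
is involved anywhere.  Perfect or quasi separation (|β| > 15) is flagged
on the estimate (HR 0 or ∞, NaN CI and p) with a warning rather than a
crash.  In dichotomized forest tables, where an in-sample optimal cutoff
routinely produces a 2×2 with an empty cell on small cohorts, the
Haldane–Anscombe continuity correction (+0.5 per cell) replaces the
logistic fit and is noted on the row — the standard zero-cell remedy for
forest plots, keeping effect sizes finite while honestly widening their
CIs.  Zero-variance variables are excluded from forest tables with a
logged reason.

Ordered outcomes (e.g. T stage 1–4) use the proportional-odds cumulative
logit model (`statsmodels` `OrderedModel`, BFGS with `gtol = 1e-10`); with
two outcome levels it reproduces the binary fit to < 10⁻⁶, which the
tests assert.  Wald p-values; significance threshold 0.05, configurable.

## Heatmap

Detection centres are floor-downscaled by the thumbnail scale factor,
accumulated (multiple centres per thumbnail pixel add), and convolved
with an isotropic Gaussian truncated at 4σ with zero-padded borders
(`scipy.ndimage.gaussian_filter`, normalized kernel).  The raw map is kept
for quantitative use — its total mass is n_detections × (truncated kernel
mass) up to border losses — and the display map is max-normalised to
[0, 1] (an all-zero map stays zero).  Defaults: σ = 2 thumbnail pixels,
`jet` colormap, α = 0.5 blend; all three are conventions of this package,
chosen for legibility.

## FROC

Detections are points with confidences.  Matching is greedy in
descending confidence: a detection is a TP if it falls inside a
ground-truth instance not yet claimed by a higher-confidence detection
(each instance claimed once; the criterion is configurable).  Greedy
claiming makes labels threshold-stable, so one pass labels all operating
points.  "Normal-region false positives" is operationalised as the mean
FP count per *benign image* (a tumour-free field).  For each FP target in
{1, 2, 4, 8, 16, 32} the operating point with the largest recall among
those with mean benign FPs ≤ target is chosen — conservative and exactly
achievable on finite data, hence oracle-checkable; a target unreachable
even with all detections uses the all-detections recall, and a target
overshot at every threshold scores recall 0.  FROC is the mean of the six
recalls.

## Synthetic scenes

The generator emulates patch-scale fields of non-overlapping elliptical
tumour cells, each with one peripherally displaced nucleus — the
signet-ring phenotype in which a mucin vacuole presses the nucleus
against the membrane.  Cell areas are lognormal (positive, right-skewed,
parameterised by arithmetic mean/SD; default 2000 ± 400 px² ≈ a 10–11 µm
equivalent radius at 0.238 µm/px); aspect ratios and NCR are normal draws
clipped into [0.05, 1] and [0.02, 0.95] (defaults 0.85 ± 0.08 and
0.25 ± 0.05).  The nucleus is a √NCR-scaled copy of its cell's ellipse,
offset along the major axis by `eccentricity × a(1 − √NCR)` — the exact
containment bound for a scaled similar ellipse — then clipped to the cell
mask, so nucleus ⊆ cell holds pixel-exactly; an optional crescent flag
subtracts a vacuole ellipse.  Placement is rejection sampling of uniform
continuous centres and orientations (overlap = any shared pixel; explicit
error after 1000 rejections naming the achieved count), and because
centres are continuous the expected pixel count of a rasterized cell
equals its target area — measured SC is unbiased.  Cohorts derive one RNG
stream per slide from `SeedSequence([master_seed, slide_index])`, so runs
are byte-reproducible and any slide can be regenerated alone.  Optional
per-slide jitter of distribution parameters models inter-patient
heterogeneity; it is what keeps group distributions overlapping in the
demo cohort so logistic effects stay finite.

What the generator does **not** emulate: touching/overlapping cells (the
boundary class path is exercised with hand-built fixtures instead),
texture or staining realism, segmentation errors, spatial clustering of
cells, or the morphology distributions of any real cohort — the supple-
mentary distributions behind the published per-group values are not
available, so generator defaults were chosen for testability.  Passing
tests therefore demonstrate correctness of the measurement and statistics
machinery on known ground truth, not fidelity to clinical data.

## Validation study sizes

The shipped studies (tests and `scripts/acceptance.py` run the same code)
use: 200 random convex blobs for the calipers-vs-sweep comparison; 100
random ellipses for area/EP recovery; 30 slides × 1000 cells for
slide-mean recovery (coverage of a 2-SE band, ~95% per slide by
construction); 50 replicate cohorts of 20 slides/group × 500 cells/slide
for power against a 1.5× mean-area shift; 100 replicate null cohorts of
10 slides/group × 100 cells/slide for type-I calibration (the level of a
slide-level t-test does not depend on cells per slide, so the null study
uses small slides); 200 replicates of n = 500 for logistic CI coverage;
and the bundled demo cohort (2 × 10 × 500, EP-SD effect with per-slide
jitter SD 0.012 against a 0.060 → 0.085 shift) for the end-to-end check.

## Known limitations

* EP is ill-conditioned near circularity (see above); between-population
  EP comparisons are meaningful mainly when populations are elongated or
  the contrast is large.
* Whether ellipticity should be short/long or long/short is a convention;
  this package fixes short/long ∈ (0, 1] (1 = round) and says so in
  output metadata.  Cutoffs, but not test decisions, depend on the
  direction.
* In-sample Youden cutoffs inflate univariate effect sizes; treat forest
  tables as descriptive unless cutoffs are externally validated.
* The FROC "normal region" is an entire benign image here; sub-image
  region definitions would change the FP axis scale.
* No WSI pyramid handling; inputs are patch-scale label images.
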