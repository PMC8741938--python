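# ringmorph

Segmentation-agnostic quantification of signet-ring-cell morphology from
instance masks: per-cell morphometry, slide-level atypia, cohort
statistics, density heatmaps and FROC detection evaluation — with a
synthetic scene generator that provides exact ground truth for every
stage.

## The problem

Signet ring cell carcinoma (SRCC) is an aggressive adenocarcinoma whose
cells carry a mucin vacuole that displaces the nucleus to the cell rim.
Given cell and nucleus instance masks for a slide (from any segmentation
model — a 4-class background/cell/nuclei/boundary semantic mask is also
accepted), each cell is reduced to four inherent properties:

* **SC** — cell cross-sectional area: the pixel count of the cell mask;
* **SN** — nucleus area: the pixel count of the assigned nucleus mask,
  where each cell takes the nucleus with the largest pixel intersection;
* **EP** — ellipticity: the aspect ratio (short/long ∈ (0, 1]) of the
  minimum-area rotated bounding rectangle of the cell mask, computed by
  convex hull + rotating calipers;
* **NCR** — nuclear/cytoplasmic ratio: SN / SC.

Per slide, the mean of each property describes typical morphology and its
standard deviation across cells quantifies **atypia** (heterogeneity).
Slides with at least 500 segmented cells enter cohort analyses, where the
package provides Welch/pooled t and Mann–Whitney U two-group tests,
Kruskal–Wallis with Tukey HSD post-hocs, dichotomization at the
Youden-optimal cutoff (max J = sensitivity + specificity − 1), univariate
logistic effect sizes (odds ratios `exp(β)` with Wald 95% CIs, labelled
"HR" as clinical reports conventionally do) in forest-table form, and
proportional-odds ordinal regression for ordered outcomes such as T
stage.  Detector output (cell-centre points with confidences) can be
rendered as a Gaussian density heatmap at thumbnail scale and scored with
the FROC metric: mean instance-level recall at 1/2/4/8/16/32 false
positives per benign image.

`docs/methods.md` documents the models, conventions, numerical choices
and limitations in detail.

## Worked example

The bundled demo cohort simulates 2 groups × 10 slides × 500 cells with
an ellipticity-atypia (EP SD) effect injected into the LN-positive group
(aspect-ratio SD 0.060 → 0.085, per-slide jitter 0.012):

```bash
ringmorph all --seed 1 --out results/demo
```

runs simulate → extract → aggregate → compare (plus a heatmap and a
synthetic-detector FROC evaluation) in about half a minute and prints the
forest table, e.g.:

```
variable      cutoff        hr   ci_low    ci_high        p                            note
 sc_mean 1988.654000  9.800000 0.438045 219.247044 0.150038 continuity-corrected (0.5/cell)
   sc_sd  369.742303  3.315789 0.120025  91.601408 0.478997 continuity-corrected (0.5/cell)
 sn_mean  489.867000  3.315789 0.120025  91.601408 0.478997 continuity-corrected (0.5/cell)
   sn_sd  137.338497  2.250000 0.170069  29.767271 0.538256
   ep_sd    0.079261 36.000000 2.721109 476.276344 0.006534
  ncr_sd    0.051293  1.714286 0.219206  13.406453 0.607507
FROC = 0.901
```

Reading it: each slide-level variable is cut at its Youden-optimal
cutoff and entered in a univariate logistic model for LN status.  The
injected effect surfaces on `ep_sd` — slides above the 0.0793 cutoff have
36× the odds of being LN-positive (95% CI 2.7–476, p = 0.0065) — while
the null variables stay non-significant.  Rows whose in-sample cutoff
isolates a pure tail (an empty 2×2 cell) carry the Haldane–Anscombe
continuity-corrected odds ratio, noted on the row.  The FROC line scores
a simulated point detector (90% sensitivity, ~3 false positives/image)
on held-out tumour and benign scenes.  Per-cell features, slide summaries, group
tests, the forest table, heatmap and FROC report land in `results/demo/`
with a reproducibility manifest.

The numbered scripts under `analysis/` walk the same pipeline step by
step on a small file-based cohort (simulate → extract features →
summarise slides → cohort statistics → heatmap → FROC), each printing
what it found and writing its tables under `results/`.

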