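"""Reusable simulation studies over the synthetic-scene pipeline.

These functions define the calibration and validation experiments the
package ships with: geometric oracle comparisons for the minimum-area
rectangle, morphometry recovery on rasterized ellipses, slide-level
parameter recovery, two-group power and type-I studies on slide-mean
cell area, confidence-interval coverage for the logistic effect sizes,
and a synthetic point detector for FROC evaluation.  Tests and the
analysis drivers call them with the same study sizes, so reported
numbers are always recomputed from scratch.

Image sizes are chosen per study so that expected cell coverage stays
near 25-30% of the field, where rejection placement is reliably fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort_stats, morphometry, synthgen
from .froc import EvalImage
from .maskio import InstanceMasks

__all__ = [
    "sweep_min_extent_area",
    "random_convex_points",
    "random_blob_mask",
    "calipers_vs_sweep_study",
    "ellipse_recovery_study",
    "image_side_for",
    "slide_mean_sc",
    "sc_recovery_study",
    "group_shift_power_study",
    "identical_groups_type1_study",
    "logit_ci_coverage_study",
    "simulate_detector",
]


# ---------------------------------------------------------------- geometry

def sweep_min_extent_area(points: np.ndarray, step_deg: float = 0.1) -> float:
    """Brute-force reference for the minimum rectangle: minimum raw
    center-extent area over a dense grid of orientations.

    The grid minimum upper-bounds the true optimum (which lies at a
    convex-hull edge direction, generally off-grid), so a correct
    calipers result is never larger than this value beyond numerical
    noise.  Independent of the calipers code path.
    """
    points = np.asarray(points, float)
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    best = math.inf
    for t in angles:
        c, s = math.cos(t), math.sin(t)
        u = points[:, 0] * c + points[:, 1] * s
        v = -points[:, 0] * s + points[:, 1] * c
        area = (u.max() - u.min()) * (v.max() - v.min())
        if area < best:
            best = area
    return float(best)


def random_convex_points(rng: np.random.Generator, n: int = 12, radius: float = 30.0) -> np.ndarray:
    """Random convex polygon vertices (hull of gaussian points), float coords."""
    pts = rng.normal(0.0, radius, size=(max(n, 4), 2))
    from scipy.spatial import ConvexHull

    return pts[ConvexHull(pts).vertices]


def random_blob_mask(rng: np.random.Generator, shape: tuple[int, int] = (96, 96)) -> np.ndarray:
    """Random rasterized convex blob: a rotated ellipse with random axes."""
    a = rng.uniform(8.0, 30.0)
    b = rng.uniform(4.0, a)
    theta = rng.uniform(0.0, math.pi)
    center = (shape[0] / 2 + rng.uniform(-5, 5), shape[1] / 2 + rng.uniform(-5, 5))
    sr, sc, inside = synthgen._ellipse_window(center, a, b, theta, shape)
    mask = np.zeros(shape, bool)
    mask[sr, sc] = inside
    return mask


def _rect_contains(points: np.ndarray, rect: morphometry.MinAreaRect, tol: float = 1e-7) -> bool:
    t = math.radians(rect.angle_deg)
    u = np.array([math.sin(t), math.cos(t)])  # long-side direction (row, col)
    v = np.array([-u[1], u[0]])
    d = points - np.asarray(rect.center)
    pu = np.abs(d @ u)
    pv = np.abs(d @ v)
    half_long = (rect.side_long - 1.0) / 2.0 + tol
    half_short = (rect.side_short - 1.0) / 2.0 + tol
    return bool((pu <= half_long).all() and (pv <= half_short).all())


def calipers_vs_sweep_study(n_blobs: int = 200, seed: int = 0) -> pd.DataFrame:
    """Compare the rotating-calipers rectangle with the 0.1-degree sweep on
    random convex blobs (half rasterized masks, half float polygons).

    Returns one row per blob with the calipers raw extent area, the sweep
    upper bound, their relative gap, and a containment check of the
    calipers rectangle.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_blobs):
        if i % 2 == 0:
            mask = random_blob_mask(rng)
            pts = np.argwhere(mask).astype(float)
            rect = morphometry.min_area_rect(mask)
        else:
            pts = random_convex_points(rng)
            rect = morphometry.min_area_rect(pts, points=True)
        sweep = sweep_min_extent_area(pts)
        gap = (rect.extent_area - sweep) / sweep if sweep > 0 else 0.0
        rows.append(
            {
                "blob": i,
                "calipers_area": rect.extent_area,
                "sweep_area": sweep,
                "relative_gap": gap,
                "contains_all": _rect_contains(pts, rect),
            }
        )
    return pd.DataFrame(rows)


def ellipse_recovery_study(n: int = 100, seed: int = 0) -> pd.DataFrame:
    """Measure rasterized random ellipses (semi-axes >= 10 px) and compare
    pixel-count area with the analytic pi*a*b and EP with b/a."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        a = rng.uniform(10.0, 40.0)
        b = rng.uniform(10.0, a)
        theta = rng.uniform(0.0, math.pi)
        pad = int(a) + 4
        shape = (2 * pad + 1, 2 * pad + 1)
        sr, sc, inside = synthgen._ellipse_window((pad, pad), a, b, theta, shape)
        mask = np.zeros(shape, bool)
        mask[sr, sc] = inside
        sc_meas = morphometry.cell_area(mask)
        ep_meas = morphometry.ellipticity(mask)
        rows.append(
            {
                "a": a,
                "b": b,
                "theta": theta,
                "area_true": math.pi * a * b,
                "area_measured": sc_meas,
                "area_rel_err": abs(sc_meas - math.pi * a * b) / (math.pi * a * b),
                "ep_true": b / a,
                "ep_measured": ep_meas,
                "ep_abs_err": abs(ep_meas - b / a),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------- cohort simulations

def image_side_for(n_cells: int, mean_area: float, coverage: float = 0.28) -> int:
    """Square field side so expected cell coverage stays near ``coverage``."""
    return int(math.ceil(math.sqrt(n_cells * mean_area / coverage)))


def slide_mean_sc(
    dist: synthgen.MorphologyDistribution,
    n_cells: int,
    seed: int,
    image_shape: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Generate one slide and return (mean, SD) of measured cell areas."""
    if image_shape is None:
        side = image_side_for(n_cells, dist.cell_area_mean)
        image_shape = (side, side)
    cell, nuc, _ = synthgen.generate_scene(
        dist, n_cells, image_shape, seed, render_nuclei=False
    )
    counts = np.bincount(cell.ravel().astype(np.int64))[1:]
    counts = counts[counts > 0].astype(float)
    return float(counts.mean()), float(counts.std(ddof=1))


def sc_recovery_study(
    n_slides: int = 30,
    cells_per_slide: int = 1000,
    mean: float = 2000.0,
    sd: float = 400.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Slide-level recovery of the true mean cell area.

    For each slide the measured slide-mean SC is compared with the
    generative mean using the slide's own standard error
    (measured SD / sqrt(n)); the ``within_2se`` flag marks agreement.
    """
    dist = synthgen.MorphologyDistribution(cell_area_mean=mean, cell_area_sd=sd)
    rows = []
    for s in range(n_slides):
        slide_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0])
        m, sdev = slide_mean_sc(dist, cells_per_slide, slide_seed)
        se = sdev / math.sqrt(cells_per_slide)
        rows.append(
            {
                "slide": s,
                "mean_sc": m,
                "sd_sc": sdev,
                "se": se,
                "within_2se": abs(m - mean) <= 2.0 * se,
            }
        )
    return pd.DataFrame(rows)


def _cohort_slide_means(
    mean_a: float,
    mean_b: float,
    sd: float,
    slides_per_group: int,
    cells_per_slide: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    dist_a = synthgen.MorphologyDistribution(cell_area_mean=mean_a, cell_area_sd=sd)
    dist_b = synthgen.MorphologyDistribution(cell_area_mean=mean_b, cell_area_sd=sd)
    means = {"a": [], "b": []}
    for g, dist in (("a", dist_a), ("b", dist_b)):
        for s in range(slides_per_group):
            slide_seed = int(
                np.random.SeedSequence([seed, 0 if g == "a" else 1, s]).generate_state(1)[0]
            )
            m, _ = slide_mean_sc(dist, cells_per_slide, slide_seed)
            means[g].append(m)
    return np.asarray(means["a"]), np.asarray(means["b"])


def group_shift_power_study(
    n_replicates: int = 50,
    slides_per_group: int = 20,
    cells_per_slide: int = 500,
    mean_a: float = 2000.0,
    ratio: float = 1.5,
    sd: float = 400.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate cohorts with a between-group mean-area shift; the t-test
    on measured slide-mean SC should detect ``ratio`` times the mean."""
    rows = []
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, 7, r]).generate_state(1)[0])
        a, b = _cohort_slide_means(
            mean_a, ratio * mean_a, sd, slides_per_group, cells_per_slide, rep_seed
        )
        _, p = cohort_stats.two_group_test(a, b, method="t")
        rows.append({"replicate": r, "p": p, "reject": p < alpha})
    return pd.DataFrame(rows)


def identical_groups_type1_study(
    n_replicates: int = 100,
    slides_per_group: int = 10,
    cells_per_slide: int = 100,
    mean: float = 2000.0,
    sd: float = 400.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate cohorts with identical group distributions; the t-test on
    slide-mean SC should reject at about the nominal rate."""
    rows = []
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, 11, r]).generate_state(1)[0])
        a, b = _cohort_slide_means(mean, mean, sd, slides_per_group, cells_per_slide, rep_seed)
        _, p = cohort_stats.two_group_test(a, b, method="t")
        rows.append({"replicate": r, "p": p, "reject": p < alpha})
    return pd.DataFrame(rows)


def logit_ci_coverage_study(
    n_replicates: int = 200,
    n: int = 500,
    odds_ratio: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Wald 95% CI coverage for the logistic odds ratio on simulated data."""
    rng = np.random.default_rng(seed)
    beta = math.log(odds_ratio)
    rows = []
    for r in range(n_replicates):
        x = rng.normal(0.0, 1.0, n)
        p = 1.0 / (1.0 + np.exp(-(beta * x)))
        y = (rng.random(n) < p).astype(float)
        if y.min() == y.max():
            rows.append({"replicate": r, "hr": np.nan, "covered": False})
            continue
        est = cohort_stats.binary_logit_hr(y, x, names=["x"])[0]
        covered = est.ci_low <= odds_ratio <= est.ci_high
        rows.append({"replicate": r, "hr": est.hr, "covered": bool(covered)})
    return pd.DataFrame(rows)


# ----------------------------------------------------- synthetic detection

def simulate_detector(
    truths: list[synthgen.SceneTruth],
    masks: list[InstanceMasks | None],
    benign_shapes: list[tuple[int, int]],
    seed: int = 0,
    sensitivity: float = 0.9,
    fp_per_image: float = 3.0,
) -> list[EvalImage]:
    """Emulate a point detector on synthetic scenes for FROC evaluation.

    Each true cell is hit with probability ``sensitivity`` at a high
    confidence; Poisson-distributed false positives with lower
    confidences land at random background positions of every image,
    including ``len(benign_shapes)`` tumour-free fields.
    """
    rng = np.random.default_rng(seed)
    images: list[EvalImage] = []

    def _fp_rows(shape: tuple[int, int], n_fp: int) -> list[dict]:
        return [
            {
                "row": rng.uniform(0, shape[0] - 1),
                "col": rng.uniform(0, shape[1] - 1),
                "confidence": rng.uniform(0.05, 0.7),
            }
            for _ in range(n_fp)
        ]

    for truth, m in zip(truths, masks):
        rows = []
        for cell in truth.cells:
            if rng.random() < sensitivity:
                rows.append(
                    {
                        "row": cell.center[0],
                        "col": cell.center[1],
                        "confidence": rng.uniform(0.5, 1.0),
                    }
                )
        rows += _fp_rows(truth.image_shape, rng.poisson(fp_per_image))
        images.append(
            EvalImage(
                image_id=truth.scene_id,
                gt_labels=m.cell_labels if m is not None else None,
                detections=pd.DataFrame(rows, columns=["row", "col", "confidence"]),
                is_benign=False,
            )
        )
    for i, shape in enumerate(benign_shapes):
        rows = _fp_rows(shape, rng.poisson(fp_per_image))
        images.append(
            EvalImage(
                image_id=f"benign-{i + 1:02d}",
                gt_labels=None,
                detections=pd.DataFrame(rows, columns=["row", "col", "confidence"]),
                is_benign=True,
            )
        )
    return images
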