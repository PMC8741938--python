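"""Synthetic signet-ring-cell scene and cohort generation.

Scenes emulate patch-scale fields of non-overlapping, roughly elliptical
tumour cells, each carrying one peripherally displaced (eccentric) nucleus
— the signet-ring morphology, where a mucin vacuole pushes the nucleus to
the cell rim.  Cells are rasterized rotated ellipses; the nucleus is a
scaled copy of its cell's ellipse offset along the major axis and clipped
to the cell, so nucleus ⊆ cell holds exactly at pixel level.  An optional
"crescent" flag subtracts a mucin-vacuole ellipse from the nucleus.

Sampling laws: cell areas are lognormal (positive, right-skewed, as cell
cross-sections in tissue are); aspect ratios (short/long) and
nuclear/cytoplasmic ratios are normal draws clipped into their valid open
intervals.  A zero SD degenerates to a constant.

Cohorts are collections of slides in named groups, each group with its own
morphology distribution and covariates; optional per-slide parameter
jitter models inter-patient heterogeneity.  All randomness flows from one
master seed via per-slide ``numpy`` seed sequences, so any slide can be
regenerated independently and cohorts are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .maskio import DEFAULT_PIXEL_SIZE, InstanceMasks, write_masks

__all__ = [
    "MorphologyDistribution",
    "CellTruth",
    "SceneTruth",
    "GroupConfig",
    "PlacementError",
    "generate_scene",
    "iter_cohort_scenes",
    "generate_cohort",
    "groups_from_dict",
]

#: ratio samples are clipped into these closed sub-intervals of their
#: valid open ranges to avoid degenerate slivers / empty nuclei
_ASPECT_CLIP = (0.05, 1.0)
_NCR_CLIP = (0.02, 0.95)


class PlacementError(RuntimeError):
    """Non-overlapping placement failed; message names the achieved count."""


@dataclass(frozen=True)
class MorphologyDistribution:
    """Per-slide sampling law for cell morphology.

    Areas in pixels; ``aspect_ratio`` is short/long in ``(0, 1]``;
    ``ncr`` is nucleus/cell area fraction in ``(0, 1)``;
    ``nucleus_eccentricity`` displaces the nucleus centre along the cell's
    major axis as a fraction of the available room (0 = concentric,
    1 = touching the cell boundary).
    """

    cell_area_mean: float = 2000.0
    cell_area_sd: float = 400.0
    aspect_ratio_mean: float = 0.85
    aspect_ratio_sd: float = 0.08
    ncr_mean: float = 0.25
    ncr_sd: float = 0.05
    nucleus_eccentricity: float = 0.6
    crescent: bool = False

    def __post_init__(self) -> None:
        if self.cell_area_mean <= 0:
            raise ValueError("cell_area_mean must be positive")
        if self.cell_area_sd < 0 or self.aspect_ratio_sd < 0 or self.ncr_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 < self.aspect_ratio_mean <= 1:
            raise ValueError("aspect_ratio_mean must lie in (0, 1]")
        if not 0 < self.ncr_mean < 1:
            raise ValueError("ncr_mean must lie in (0, 1)")
        if not 0 <= self.nucleus_eccentricity < 1:
            raise ValueError("nucleus_eccentricity must lie in [0, 1)")


@dataclass(frozen=True)
class CellTruth:
    """Generative parameters of one placed cell."""

    cell_id: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b
    orientation: float  # radians, major axis from the column axis
    nucleus_center: tuple[float, float]
    nucleus_semi_axes: tuple[float, float]
    target_area: float
    target_aspect: float
    target_ncr: float


@dataclass
class SceneTruth:
    """Exact ground truth of a generated scene."""

    scene_id: str
    image_shape: tuple[int, int]
    cells: list[CellTruth]
    is_benign: bool
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scene_id": self.scene_id,
                "cell_id": [c.cell_id for c in self.cells],
                "row": [c.center[0] for c in self.cells],
                "col": [c.center[1] for c in self.cells],
                "semi_a": [c.semi_axes[0] for c in self.cells],
                "semi_b": [c.semi_axes[1] for c in self.cells],
                "orientation": [c.orientation for c in self.cells],
                "target_area": [c.target_area for c in self.cells],
                "target_aspect": [c.target_aspect for c in self.cells],
                "target_ncr": [c.target_ncr for c in self.cells],
            }
        )


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    return np.clip(rng.normal(mean, sd, n), lo, hi)


def _ellipse_window(
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
    shape: tuple[int, int],
) -> tuple[slice, slice, np.ndarray]:
    """Window slices and a boolean inset of pixel centers inside a rotated
    ellipse, clipped to the image shape."""
    cr, cc = center
    half = int(math.ceil(a)) + 1
    r0 = max(int(math.floor(cr)) - half, 0)
    r1 = min(int(math.ceil(cr)) + half, shape[0] - 1)
    c0 = max(int(math.floor(cc)) - half, 0)
    c1 = min(int(math.ceil(cc)) + half, shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), bool)
    rr = np.arange(r0, r1 + 1)[:, None] - cr
    cc_ = np.arange(c0, c1 + 1)[None, :] - cc
    s, c = math.sin(theta), math.cos(theta)
    p = rr * s + cc_ * c  # along major axis
    q = rr * c - cc_ * s
    inside = (p * p) * (1.0 / (a * a)) + (q * q) * (1.0 / (b * b)) <= 1.0
    return slice(r0, r1 + 1), slice(c0, c1 + 1), inside


def _ellipse_pixels(
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixel centers inside a rotated ellipse, clipped to shape."""
    sr, sc_, inside = _ellipse_window(center, a, b, theta, shape)
    ri, ci = np.nonzero(inside)
    return ri + sr.start, ci + sc_.start


def generate_scene(
    dist: MorphologyDistribution,
    n_cells: int,
    image_shape: tuple[int, int],
    seed: int,
    *,
    scene_id: str = "scene",
    max_rejections: int = 1000,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    render_nuclei: bool = True,
) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Generate one scene: cell label mask, nucleus label mask, ground truth.

    Cells are placed by rejection sampling (uniform continuous centres,
    uniform orientations); overlap means any shared pixel.  After
    ``max_rejections`` failed draws for a single cell a
    :class:`PlacementError` names the number of cells placed so far.
    Identical ``(dist, n_cells, image_shape, seed)`` give bit-identical
    masks.

    ``render_nuclei=False`` skips nucleus rasterization (the nucleus mask
    comes back empty) for large area-only simulation studies; cell masks
    and the random stream are unaffected.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rows, cols = image_shape
    rng = np.random.default_rng(seed)

    cell_labels = np.zeros(image_shape, dtype=np.uint16)
    nucleus_labels = np.zeros(image_shape, dtype=np.uint16)
    truth = SceneTruth(scene_id, (int(rows), int(cols)), [], n_cells == 0, int(seed))
    if n_cells == 0:
        return cell_labels, nucleus_labels, truth

    areas = _lognormal(rng, dist.cell_area_mean, dist.cell_area_sd, n_cells)
    aspects = _clipped_normal(rng, dist.aspect_ratio_mean, dist.aspect_ratio_sd, n_cells, *_ASPECT_CLIP)
    ncrs = _clipped_normal(rng, dist.ncr_mean, dist.ncr_sd, n_cells, *_NCR_CLIP)
    thetas = rng.uniform(0.0, math.pi, n_cells)
    nuc_sides = rng.choice([-1.0, 1.0], n_cells)

    occupied = np.zeros(image_shape, dtype=bool)
    for i in range(n_cells):
        area, q, theta = areas[i], aspects[i], thetas[i]
        a = math.sqrt(area / (math.pi * q))
        b = q * a
        margin = a + 1.0
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError(
                f"image {image_shape} too small for a cell with semi-major axis "
                f"{a:.1f}px; placed {i} of {n_cells} cells"
            )
        placed = False
        for _ in range(max_rejections):
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            sr, sc_, inside = _ellipse_window((cr, cc), a, b, theta, image_shape)
            if inside.size == 0 or not inside.any():
                continue
            occ_win = occupied[sr, sc_]
            if (occ_win & inside).any():
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} after {max_rejections} "
                f"rejections; placed {i} cells — enlarge the image or reduce density"
            )
        label = i + 1
        occupied[sr, sc_] |= inside
        cell_win = cell_labels[sr, sc_]
        cell_win[inside] = label

        # nucleus: scaled copy offset along the major axis, clipped to the cell
        s_ratio = math.sqrt(ncrs[i])
        an, bn = s_ratio * a, s_ratio * b
        offset = dist.nucleus_eccentricity * a * (1.0 - s_ratio) * nuc_sides[i]
        ncr_center = (cr + offset * math.sin(theta), cc + offset * math.cos(theta))
        if render_nuclei:
            nsr, nsc, n_inside = _ellipse_window(ncr_center, an, bn, theta, image_shape)
            if n_inside.size:
                n_inside &= cell_labels[nsr, nsc] == label  # clip to the cell
            if dist.crescent and n_inside.any():
                # mucin vacuole on the opposite side eats into the nucleus
                voff = -0.25 * a * nuc_sides[i]
                vc = (cr + voff * math.sin(theta), cc + voff * math.cos(theta))
                vsr, vsc, v_inside = _ellipse_window(vc, 0.75 * a, 0.75 * b, theta, image_shape)
                vac = np.zeros(image_shape, dtype=bool)
                vac[vsr, vsc] = v_inside
                carved = n_inside & ~vac[nsr, nsc]
                if carved.any():  # never erase the nucleus entirely
                    n_inside = carved
            nuc_win = nucleus_labels[nsr, nsc]
            nuc_win[n_inside] = label

        truth.cells.append(
            CellTruth(
                cell_id=label,
                center=(cr, cc),
                semi_axes=(a, b),
                orientation=theta,
                nucleus_center=ncr_center,
                nucleus_semi_axes=(an, bn),
                target_area=float(area),
                target_aspect=float(q),
                target_ncr=float(ncrs[i]),
            )
        )
    return cell_labels, nucleus_labels, truth


@dataclass
class GroupConfig:
    """One cohort group: a morphology law plus shared covariates.

    ``slide_jitter`` maps :class:`MorphologyDistribution` field names to a
    normal SD applied per slide (inter-patient heterogeneity); jittered
    values are clipped into the field's valid range.
    """

    name: str
    dist: MorphologyDistribution
    n_slides: int
    cells_per_slide: int
    image_shape: tuple[int, int] = (1500, 1500)
    covariates: dict = field(default_factory=dict)
    slide_jitter: dict = field(default_factory=dict)


_JITTER_BOUNDS = {
    "cell_area_mean": (1.0, math.inf),
    "cell_area_sd": (0.0, math.inf),
    "aspect_ratio_mean": (0.05, 1.0),
    "aspect_ratio_sd": (0.0, 0.5),
    "ncr_mean": (0.02, 0.95),
    "ncr_sd": (0.0, 0.5),
    "nucleus_eccentricity": (0.0, 0.99),
}


def _jittered(dist: MorphologyDistribution, jitter: dict, rng: np.random.Generator) -> MorphologyDistribution:
    if not jitter:
        return dist
    updates = {}
    for name, sd in jitter.items():
        if name not in _JITTER_BOUNDS:
            raise ValueError(f"unknown jitter parameter: {name}")
        lo, hi = _JITTER_BOUNDS[name]
        updates[name] = float(np.clip(getattr(dist, name) + rng.normal(0.0, sd), lo, hi))
    return replace(dist, **updates)


def iter_cohort_scenes(
    groups: Sequence[GroupConfig],
    seed: int,
) -> Iterator[tuple[str, GroupConfig, InstanceMasks, SceneTruth]]:
    """Yield ``(slide_id, group, masks, truth)`` for every slide of a cohort.

    Slide seeds derive from ``SeedSequence([seed, slide_index])`` so each
    slide is independently reproducible.
    """
    if not groups:
        raise ValueError("at least one group is required")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    index = 0
    for group in groups:
        for s in range(group.n_slides):
            slide_id = f"{group.name}-s{s + 1:02d}"
            ss = np.random.SeedSequence([int(seed), index])
            scene_seed, jitter_seed = (int(x) for x in ss.generate_state(2))
            dist = _jittered(group.dist, group.slide_jitter, np.random.default_rng(jitter_seed))
            cell, nuc, truth = generate_scene(
                dist,
                group.cells_per_slide,
                group.image_shape,
                scene_seed,
                scene_id=slide_id,
            )
            yield slide_id, group, InstanceMasks(cell, nuc), truth
            index += 1


def generate_cohort(
    groups: Sequence[GroupConfig],
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort; returns ``(covariates, truth_table)``.

    With ``outdir`` set, masks are written as ``<slide>_cells.tif`` /
    ``<slide>_nuclei.tif`` alongside ``covariates.csv`` and ``truth.csv``.
    """
    cov_rows = []
    truth_frames = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    for slide_id, group, masks, truth in iter_cohort_scenes(groups, seed):
        if slide_id in seen:
            raise ValueError(f"duplicate slide id: {slide_id}")
        seen.add(slide_id)
        cov_rows.append({"slide_id": slide_id, "group": group.name, **group.covariates})
        truth_frames.append(truth.to_frame())
        if out is not None:
            write_masks(masks, out / f"{slide_id}_cells.tif", out / f"{slide_id}_nuclei.tif")
    covariates = pd.DataFrame(cov_rows)
    truth_table = (
        pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame()
    )
    if out is not None:
        covariates.to_csv(out / "covariates.csv", index=False)
        truth_table.to_csv(out / "truth.csv", index=False)
    return covariates, truth_table


def groups_from_dict(config: dict) -> list[GroupConfig]:
    """Build :class:`GroupConfig` objects from a parsed YAML/JSON mapping."""
    groups = []
    for entry in config["groups"]:
        dist = MorphologyDistribution(**entry.get("dist", {}))
        groups.append(
            GroupConfig(
                name=str(entry["name"]),
                dist=dist,
                n_slides=int(entry["n_slides"]),
                cells_per_slide=int(entry["cells_per_slide"]),
                image_shape=tuple(entry.get("image_shape", (1500, 1500))),
                covariates=dict(entry.get("covariates", {})),
                slide_jitter=dict(entry.get("slide_jitter", {})),
            )
        )
    return groups
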