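"""Per-cell morphometry from instance label masks.

Four inherent properties are measured for every segmented signet ring cell:

* ``SC`` — cell cross-sectional area, the raw pixel count of the cell mask;
* ``SN`` — nucleus area, the pixel count of the assigned nucleus mask;
* ``EP`` — ellipticity, the aspect ratio (short/long, in ``(0, 1]``) of the
  minimum-area rotated bounding rectangle of the cell mask;
* ``NCR`` — nuclear/cytoplasmic ratio, ``SN / SC``.

Each cell is assigned the nucleus instance with the largest pixel overlap;
a nucleus may serve several cells (the rule is applied per cell), and cells
with no overlapping nucleus carry null ``SN``/``NCR``.

The minimum-area rectangle is computed from the convex hull of the pixel
*centers* by rotating calipers (the optimal rectangle has a side collinear
with a hull edge).  Reported side lengths add one pixel to the center
extents so that an axis-aligned ``r x c`` block of pixels measures exactly
``(max(r,c), min(r,c))``; degenerate (single-pixel or collinear) masks
report a short side of 1 pixel by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

from .maskio import InstanceMasks

__all__ = [
    "CellRecord",
    "MinAreaRect",
    "cell_area",
    "min_area_rect",
    "ellipticity",
    "assign_nuclei",
    "extract_features",
    "area_table",
    "features_to_frame",
]


@dataclass(frozen=True)
class MinAreaRect:
    """Minimum-area rotated bounding rectangle of a set of pixel centers.

    ``side_long >= side_short`` are the pixel-footprint side lengths
    (center extent + 1).  ``angle_deg`` is the orientation of the long
    side in degrees, measured from the column axis, in ``[0, 180)``.
    ``extent_area`` is the raw product of the center extents at the
    optimal orientation (the quantity minimised by the calipers search);
    it is 0 for degenerate masks.
    """

    center: tuple[float, float]
    side_long: float
    side_short: float
    angle_deg: float
    extent_area: float

    @property
    def area(self) -> float:
        return self.side_long * self.side_short


def _as_points(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise ValueError("mask is empty: no foreground pixels")
    return pts.astype(float)


def cell_area(mask: np.ndarray) -> int:
    """Pixel count of a single-instance binary mask (errors on empty)."""
    return int(_as_points(mask).shape[0])


def _rect_from_direction(points: np.ndarray, u: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Extents (w >= h), raw area and center of the bbox aligned with unit vector u."""
    v = np.array([-u[1], u[0]])
    pu = points @ u
    pv = points @ v
    w = pu.max() - pu.min()
    h = pv.max() - pv.min()
    cu = (pu.max() + pu.min()) / 2.0
    cv = (pv.max() + pv.min()) / 2.0
    center = cu * u + cv * v
    return w, h, w * h, center


def min_area_rect(mask_or_points: np.ndarray, *, points: bool = False) -> MinAreaRect:
    """Minimum-area rotated bounding rectangle via convex hull + rotating calipers.

    Parameters
    ----------
    mask_or_points
        Binary mask of one instance, or — with ``points=True`` — an
        ``(n, 2)`` float array of ``(row, col)`` coordinates.

    The search minimises the raw center-extent area over all convex-hull
    edge directions, which contains the global optimum.  Side lengths are
    reported with the +1 pixel-footprint convention.
    """
    if points:
        pts = np.asarray(mask_or_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (n, 2) array")
    else:
        pts = _as_points(mask_or_points)

    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] == 1:
        r, c = uniq[0]
        return MinAreaRect((float(r), float(c)), 1.0, 1.0, 0.0, 0.0)

    try:
        hull = ConvexHull(uniq)
        hull_pts = uniq[hull.vertices]
    except QhullError:
        # collinear points: long side spans the principal direction
        centered = uniq - uniq.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        u = vt[0]
        proj = centered @ u
        length = proj.max() - proj.min()
        ang = math.degrees(math.atan2(u[0], u[1])) % 180.0
        return MinAreaRect(
            (float(uniq[:, 0].mean()), float(uniq[:, 1].mean())),
            length + 1.0,
            1.0,
            ang,
            0.0,
        )

    n = hull_pts.shape[0]
    best = None
    for i in range(n):
        edge = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        u = edge / norm
        w, h, raw, center = _rect_from_direction(hull_pts, u)
        if best is None or raw < best[2] - 1e-12:
            best = (w, h, raw, center, u)
    assert best is not None
    w, h, raw, center, u = best
    if w < h:
        w, h = h, w
        u = np.array([-u[1], u[0]])
    ang = math.degrees(math.atan2(u[0], u[1])) % 180.0
    return MinAreaRect(
        (float(center[0]), float(center[1])),
        float(w + 1.0),
        float(h + 1.0),
        float(ang),
        float(raw),
    )


def ellipticity(mask: np.ndarray) -> float:
    """EP = short/long side of the minimum-area rotated box, in ``(0, 1]``."""
    rect = min_area_rect(mask)
    return rect.side_short / rect.side_long


def assign_nuclei(masks: InstanceMasks) -> dict[int, Optional[int]]:
    """Assign to each cell the nucleus with the largest pixel intersection.

    Overlaps are counted on the raw label images.  Ties break toward the
    smallest nucleus id; a nucleus may be assigned to several cells.
    Cells whose mask intersects no nucleus map to ``None``.
    """
    cells = masks.cell_labels
    nucs = masks.nucleus_labels
    both = (cells > 0) & (nucs > 0)
    cell_ids = [int(i) for i in np.unique(cells) if i > 0]
    assignment: dict[int, Optional[int]] = {cid: None for cid in cell_ids}
    if not both.any():
        return assignment
    pairs = np.stack([cells[both], nucs[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    # sort so that for each cell the best (count desc, nucleus id asc) comes first
    order = np.lexsort((uniq[:, 1], -counts, uniq[:, 0]))
    seen: set[int] = set()
    for idx in order:
        cid = int(uniq[idx, 0])
        if cid in seen:
            continue
        seen.add(cid)
        assignment[cid] = int(uniq[idx, 1])
    return assignment


@dataclass
class CellRecord:
    """Measured inherent properties of one segmented cell."""

    cell_id: int
    sc: int
    centroid: tuple[float, float]
    ep: float
    nucleus_id: Optional[int] = None
    sn: Optional[int] = None
    ncr: Optional[float] = None


def extract_features(masks: InstanceMasks) -> list[CellRecord]:
    """One :class:`CellRecord` per cell instance, ordered by cell id.

    ``SN``/``NCR`` are null for cells without an assigned nucleus; such
    cells still contribute to SC/EP statistics downstream.
    """
    assignment = assign_nuclei(masks)
    nuc_areas = np.bincount(masks.nucleus_labels.ravel())
    records: list[CellRecord] = []
    for prop in regionprops(masks.cell_labels):
        cid = int(prop.label)
        rect = min_area_rect(prop.coords.astype(float), points=True)
        ep = rect.side_short / rect.side_long
        nid = assignment.get(cid)
        sn = None
        ncr = None
        if nid is not None and nid < len(nuc_areas):
            sn = int(nuc_areas[nid])
            ncr = sn / prop.area
        records.append(
            CellRecord(
                cell_id=cid,
                sc=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                ep=float(ep),
                nucleus_id=nid,
                sn=sn,
                ncr=ncr,
            )
        )
    records.sort(key=lambda r: r.cell_id)
    return records


def area_table(masks: InstanceMasks, slide_id: str | None = None) -> pd.DataFrame:
    """Fast per-cell SC/SN/NCR table via label histograms (no shape features).

    Assumes nucleus labels match cell labels (as the synthetic generator
    and :func:`ringmorph.maskio.semantic_to_instances` guarantee); for
    arbitrary label pairings use :func:`extract_features`.
    """
    sc = np.bincount(masks.cell_labels.ravel().astype(np.int64))
    sn = np.bincount(masks.nucleus_labels.ravel().astype(np.int64), minlength=sc.size)[: sc.size]
    ids = np.flatnonzero(sc[1:]) + 1
    sc_v = sc[ids].astype(int)
    sn_v = sn[ids].astype(float)
    sn_v[sn_v == 0] = np.nan
    df = pd.DataFrame({"cell_id": ids, "sc": sc_v, "sn": sn_v, "ncr": sn_v / sc_v})
    if slide_id is not None:
        df.insert(0, "slide_id", slide_id)
    return df


def features_to_frame(records: list[CellRecord], slide_id: str | None = None) -> pd.DataFrame:
    """Tidy per-cell feature table (one row per cell)."""
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "row": [r.centroid[0] for r in records],
            "col": [r.centroid[1] for r in records],
            "sc": [r.sc for r in records],
            "sn": [r.sn for r in records],
            "ep": [r.ep for r in records],
            "ncr": [r.ncr for r in records],
        }
    )
    if slide_id is not None:
        df.insert(0, "slide_id", slide_id)
    return df
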