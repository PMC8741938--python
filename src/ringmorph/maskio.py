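"""Label-mask and table I/O, plus 4-class semantic-mask conversion.

Masks are dense 2-D integer label images (0 = background), written as
16/32-bit TIFF or 8-bit PNG (PNG only up to 255 labels).  Detection and
feature tables are plain CSV (comma, header row, UTF-8).  Coordinates are
0-based ``(row, col)``.

Segmentation networks in this problem emit a 4-class semantic mask —
background / cell / nuclei / instance-boundary — where the boundary class
separates touching cells; :func:`semantic_to_instances` recovers instance
label images from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage
from skimage.measure import label as _cc_label

#: classes of the semantic mask convention
BACKGROUND, CELL, NUCLEI, BOUNDARY = 0, 1, 2, 3

#: microns per pixel of a x40 scan, used only for optional unit reporting
DEFAULT_PIXEL_SIZE = 0.238

__all__ = [
    "InstanceMasks",
    "semantic_to_instances",
    "read_masks",
    "write_masks",
    "read_detections",
    "write_detections",
    "DEFAULT_PIXEL_SIZE",
]


@dataclass
class InstanceMasks:
    """Paired cell / nucleus instance label images of one field.

    Labels are positive integers, 0 is background.  A nucleus shares the
    label of the cell it was generated or derived for when the source
    guarantees pairing; otherwise pairing is established downstream by
    largest-intersection assignment.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        for name, arr in (("cell", self.cell_labels), ("nucleus", self.nucleus_labels)):
            if arr.ndim != 2:
                raise ValueError(f"{name} labels must be 2-D, got shape {arr.shape}")
            if not np.issubdtype(arr.dtype, np.integer):
                raise TypeError(f"{name} labels must be integer-typed, got {arr.dtype}")
            if arr.min(initial=0) < 0:
                raise ValueError(f"{name} labels contain negative values")
        if self.cell_labels.shape != self.nucleus_labels.shape:
            raise ValueError(
                f"shape mismatch: cell {self.cell_labels.shape} vs "
                f"nucleus {self.nucleus_labels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_labels.shape

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.cell_labels))) - int(0 in self.cell_labels)


def _relabel_by_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel components 1..k ordered by their first pixel in row-major scan."""
    out = np.zeros_like(labels)
    flat = labels.ravel()
    fg = np.flatnonzero(flat)
    if fg.size == 0:
        return out
    # first occurrence of each label in scan order
    order: dict[int, int] = {}
    for pos in fg:
        lab = int(flat[pos])
        if lab not in order:
            order[lab] = len(order) + 1
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for old, new in order.items():
        lut[old] = new
    out = lut[labels]
    return out


def semantic_to_instances(
    semantic: np.ndarray,
    *,
    connectivity: int = 8,
    assign_boundary: bool = True,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> InstanceMasks:
    """Convert a 4-class semantic mask into cell/nucleus instance labels.

    Connected components of cell+nuclei pixels (boundary pixels removed)
    become cell instances; the nuclei pixels of a component become its
    nucleus instance under the same label.  Boundary pixels are then
    attributed to the geodesically nearest instance (iterative
    8-neighbour flooding restricted to boundary pixels; ties go to the
    smallest label), or left unassigned with ``assign_boundary=False``.

    Labels are contiguous from 1, ordered by each component's first pixel
    in row-major scan order.
    """
    semantic = np.asarray(semantic)
    if semantic.ndim != 2:
        raise ValueError("semantic mask must be 2-D")
    bad = np.setdiff1d(np.unique(semantic), [BACKGROUND, CELL, NUCLEI, BOUNDARY])
    if bad.size:
        raise ValueError(f"semantic mask contains invalid class values: {bad.tolist()}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    interior = (semantic == CELL) | (semantic == NUCLEI)
    cc = _cc_label(interior, connectivity=2 if connectivity == 8 else 1)
    cells = _relabel_by_scan_order(cc)
    nuclei = np.where(semantic == NUCLEI, cells, 0)

    if assign_boundary:
        boundary = semantic == BOUNDARY
        cells = cells.astype(np.int64)
        big = int(cells.max()) + 1  # sentinel above every real label
        while True:
            unassigned = boundary & (cells == 0)
            if not unassigned.any():
                break
            padded = np.where(cells > 0, cells, big)
            # min over the 8-neighbourhood -> smallest adjacent label
            nearest = ndimage.grey_erosion(padded, size=(3, 3), mode="constant", cval=big)
            grow = unassigned & (nearest < big)
            if not grow.any():
                break  # boundary pixels not connected to any instance
            cells[grow] = nearest[grow]

    dtype = np.uint16 if cells.max() < 2**16 else np.int32
    return InstanceMasks(cells.astype(dtype), nuclei.astype(dtype), pixel_size=pixel_size)


def _write_label_image(arr: np.ndarray, path: Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        out = arr.astype(np.uint16 if arr.max(initial=0) < 2**16 else np.uint32)
        tifffile.imwrite(path, out)
    elif suffix == ".png":
        if arr.max(initial=0) > 255:
            raise ValueError(
                f"{path.name}: {int(arr.max())} labels exceed 8-bit PNG capacity "
                "(255); write a TIFF instead"
            )
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported mask format: {suffix} (use .tif/.tiff/.png)")


def _read_label_image(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path.name}: label image must be integer-typed, got {arr.dtype}")
    return arr.astype(np.int_) if arr.dtype.kind == "u" and arr.dtype.itemsize >= 4 else arr


def write_masks(masks: InstanceMasks, cell_path: str | Path, nucleus_path: str | Path) -> None:
    _write_label_image(masks.cell_labels, Path(cell_path))
    _write_label_image(masks.nucleus_labels, Path(nucleus_path))


def read_masks(
    cell_path: str | Path,
    nucleus_path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> InstanceMasks:
    cell = _read_label_image(Path(cell_path))
    nuc = _read_label_image(Path(nucleus_path))
    return InstanceMasks(cell, nuc, pixel_size=pixel_size)


_DETECTION_COLUMNS = ["image_id", "row", "col", "confidence"]


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _DETECTION_COLUMNS if c not in detections.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    detections[_DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: detection table missing columns: {missing}")
    conf = df["confidence"].to_numpy(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError(f"{path}: confidences outside [0, 1]")
    return df
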