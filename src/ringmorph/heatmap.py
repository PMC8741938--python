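"""Gaussian density heatmaps of detected cells at thumbnail scale.

Full-resolution detection coordinates are floor-downscaled into a
thumbnail-sized accumulator (multiple detections in one thumbnail pixel
add up), which is then convolved with an isotropic Gaussian kernel
(truncated at 4 sigma, zero-padded borders).  The raw accumulation map is
preserved for quantitative use; the display map is max-normalised to
[0, 1] so regions dense in signet ring cells light up against the
thumbnail when alpha-blended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage

__all__ = ["HeatmapSpec", "gaussian_map", "kernel_mass", "overlay"]

_TRUNCATE = 4.0


@dataclass(frozen=True)
class HeatmapSpec:
    """Geometry of the thumbnail map.

    ``scale_factor`` is the full-resolution-to-thumbnail ratio (>= 1);
    ``sigma`` is the Gaussian SD in thumbnail pixels.
    """

    thumbnail_shape: tuple[int, int]
    scale_factor: float = 32.0
    sigma: float = 2.0
    blend_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.blend_alpha <= 1:
            raise ValueError("blend_alpha must lie in [0, 1]")


def kernel_mass(sigma: float, truncate: float = _TRUNCATE) -> float:
    """Sum of the discrete truncated Gaussian kernel (the mass one
    detection contributes to the raw map, slightly below 1)."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return float(np.outer(k, k).sum())


def gaussian_map(
    centers: np.ndarray,
    spec: HeatmapSpec,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Density map of full-resolution ``(row, col)`` centers.

    Returns the max-normalised map in [0, 1] by default, or the raw
    convolved accumulation with ``normalize=False`` (its total mass is
    ``n_centers * kernel_mass(sigma)`` up to border losses).  An all-zero
    map stays zero.  Centers outside the full-resolution bounds raise,
    listing the offenders.
    """
    centers = np.asarray(centers, float).reshape(-1, 2)
    rows, cols = spec.thumbnail_shape
    full_r = rows * spec.scale_factor
    full_c = cols * spec.scale_factor
    if centers.size:
        bad = (
            (centers[:, 0] < 0)
            | (centers[:, 0] >= full_r)
            | (centers[:, 1] < 0)
            | (centers[:, 1] >= full_c)
        )
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} center(s) outside full-resolution bounds "
                f"({full_r:.0f} x {full_c:.0f}): {centers[bad][:5].tolist()}"
            )
    acc = np.zeros((rows, cols), dtype=np.float64)
    if centers.size:
        idx_r = np.floor(centers[:, 0] / spec.scale_factor).astype(int)
        idx_c = np.floor(centers[:, 1] / spec.scale_factor).astype(int)
        np.add.at(acc, (idx_r, idx_c), 1.0)
    out = ndimage.gaussian_filter(acc, spec.sigma, mode="constant", truncate=_TRUNCATE)
    if normalize:
        peak = out.max()
        if peak > 0:
            out = out / peak
    return out


def overlay(
    thumbnail: np.ndarray,
    intensity: np.ndarray,
    blend_alpha: float = 0.5,
    colormap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a colormapped intensity map over an RGB thumbnail.

    ``blend_alpha=0`` returns the thumbnail unchanged; the blend is
    pixel-wise convex, so every output channel lies between the
    thumbnail's and the colormapped map's channels.
    """
    thumbnail = np.asarray(thumbnail)
    intensity = np.asarray(intensity, float)
    if thumbnail.ndim != 3 or thumbnail.shape[2] != 3:
        raise ValueError("thumbnail must be an (r, c, 3) RGB image")
    if thumbnail.shape[:2] != intensity.shape:
        raise ValueError(
            f"shape mismatch: thumbnail {thumbnail.shape[:2]} vs map {intensity.shape}"
        )
    if not 0 <= blend_alpha <= 1:
        raise ValueError("blend_alpha must lie in [0, 1]")
    cmap = colormaps[colormap]
    colored = cmap(np.clip(intensity, 0.0, 1.0))[..., :3] * 255.0
    blended = (1.0 - blend_alpha) * thumbnail.astype(float) + blend_alpha * colored
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
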