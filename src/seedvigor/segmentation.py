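"""Per-seed ROI extraction from a calibrated cube.

The pipeline mirrors the standard single-band segmentation recipe for seed
scenes: pick the band nearest 635.77 nm (seeds show crisp outlines there),
median-filter and min–max rescale, Otsu-threshold into a binary mask, clean
it with one 3x3 morphological opening, then label 8-connected components.
Each component above the minimum area becomes a :class:`SeedROI` carrying its
mask, centroid, a 46x46 crop of the full cube centered on the centroid
(zero-padded at scene edges) and the ROI-averaged spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .hypercube import Hypercube, band_at_wavelength

__all__ = [
    "SeedROI",
    "gray_band_image",
    "enhance",
    "otsu_threshold",
    "binarize",
    "extract_seed_rois",
    "mean_spectrum",
    "roi_table",
    "spectra_table",
]

DEFAULT_SEGMENTATION_NM = 635.77
DEFAULT_MIN_AREA = 20
DEFAULT_CROP = 46

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SeedROI:
    """One seed's mask, bounding box, crop stack and mean spectrum."""

    seed_id: int
    mask: np.ndarray  # boolean, scene coordinates
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1 (half-open)
    centroid: tuple[float, float]
    crop: np.ndarray  # crop x crop x w
    mean_spectrum: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def gray_band_image(cube: Hypercube, target_nm: float = DEFAULT_SEGMENTATION_NM) -> np.ndarray:
    """Single-band grayscale plane at the band nearest ``target_nm``."""
    return np.asarray(cube.data[:, :, band_at_wavelength(cube, target_nm)], dtype=float)


def enhance(gray: np.ndarray) -> np.ndarray:
    """3x3 median filter followed by min–max rescale to [0, 1].

    A constant image cannot be rescaled; it is returned unchanged (after
    filtering, which is a no-op on constants).
    """
    if not np.all(np.isfinite(gray)):
        raise ValueError("image contains non-finite values")
    filtered = ndimage.median_filter(gray, size=3)
    lo, hi = filtered.min(), filtered.max()
    if hi == lo:
        return filtered
    return (filtered - lo) / (hi - lo)


def otsu_threshold(gray: np.ndarray, levels: int = 256) -> float:
    """Otsu's threshold over a ``levels``-bin histogram of the image.

    Returns the bin edge maximizing between-class variance; pixels strictly
    above the threshold are foreground. Ties break to the lowest threshold.
    """
    gray = np.asarray(gray, dtype=float)
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        raise ValueError("constant image has no Otsu threshold")
    hist, edges = np.histogram(gray, bins=levels, range=(lo, hi))
    p = hist / hist.sum()
    omega = np.cumsum(p)  # class-0 probability up to bin k
    mu = np.cumsum(p * np.arange(levels))  # first moment up to bin k
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # first maximum -> lowest threshold
    return float(edges[k + 1])  # upper edge of bin k: class 0 is <= threshold


def binarize(gray: np.ndarray, levels: int = 256, opening: bool = True) -> np.ndarray:
    """Otsu binarization plus one 3x3 opening to drop specks."""
    mask = gray > otsu_threshold(gray, levels=levels)
    if opening:
        mask = ndimage.binary_opening(mask, structure=_EIGHT_CONN)
    return mask


def mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the cube over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("empty mask")
    return cube.data[mask].mean(axis=0)


def _centered_crop(cube_data: np.ndarray, center: tuple[float, float], size: int) -> np.ndarray:
    """Crop ``size x size`` around ``center``, zero-padded at the scene edges."""
    h, w, nb = cube_data.shape
    r0 = int(round(center[0])) - size // 2
    c0 = int(round(center[1])) - size // 2
    out = np.zeros((size, size, nb), dtype=cube_data.dtype)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    out[rs - r0 : re - r0, cs - c0 : ce - c0] = cube_data[rs:re, cs:ce]
    return out


def extract_seed_rois(
    cube: Hypercube,
    binary: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    crop: int = DEFAULT_CROP,
) -> list[SeedROI]:
    """Label 8-connected components of the mask and build per-seed ROIs.

    Components below ``min_area`` are dropped; the survivors are numbered
    row-major by centroid (stable seed numbering across runs).
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != cube.data.shape[:2]:
        raise ValueError("binary mask shape does not match cube spatial shape")
    labeled, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 0:
        return []
    areas = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    keep = [i + 1 for i in range(n) if areas[i] >= min_area]
    if not keep:
        return []
    centroids = ndimage.center_of_mass(binary, labeled, index=keep)
    order = sorted(
        range(len(keep)), key=lambda i: (round(centroids[i][0]), centroids[i][1])
    )
    rois = []
    for new_id, idx in enumerate(order, start=1):
        comp = labeled == keep[idx]
        rows, cols = np.nonzero(comp)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        rois.append(
            SeedROI(
                seed_id=new_id,
                mask=comp,
                bbox=bbox,
                centroid=centroids[idx],
                crop=_centered_crop(cube.data, centroids[idx], crop),
                mean_spectrum=mean_spectrum(cube, comp),
            )
        )
    return rois


def segment_scene(
    cube: Hypercube,
    target_nm: float = DEFAULT_SEGMENTATION_NM,
    min_area: int = DEFAULT_MIN_AREA,
    crop: int = DEFAULT_CROP,
) -> list[SeedROI]:
    """Full pipeline: gray band -> enhance -> Otsu+opening -> ROIs."""
    gray = enhance(gray_band_image(cube, target_nm))
    return extract_seed_rois(cube, binarize(gray), min_area=min_area, crop=crop)


def roi_table(rois: list[SeedROI]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seed_id": [r.seed_id for r in rois],
            "centroid_row": [r.centroid[0] for r in rois],
            "centroid_col": [r.centroid[1] for r in rois],
            "area": [r.area for r in rois],
        }
    )


def spectra_table(rois: list[SeedROI], wavelengths: np.ndarray) -> pd.DataFrame:
    """Wide table of mean spectra: one row per seed, one column per band."""
    df = pd.DataFrame(
        np.stack([r.mean_spectrum for r in rois]),
        columns=[f"{w:.2f}" for w in wavelengths],
    )
    df.insert(0, "seed_id", [r.seed_id for r in rois])
    return df
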