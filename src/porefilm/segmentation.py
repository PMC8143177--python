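"""Cleanup and region extraction after pixel classification.

Stages, in pipeline order: 5x5 median despeckling of the hole-cluster
rendering, Otsu binarization, small-region elimination, connected-component
labeling, and Sobel edge extraction.  All window operations replicate edge
pixels at the border so outputs keep the input dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RANGE_8BIT, BinaryMask, RasterImage


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on the given image (e.g. constant)."""


@dataclass(frozen=True)
class LabeledRegions:
    """Connected-component labeling: 0 = background, 1..n_regions = regions."""

    labels: np.ndarray
    n_regions: int
    connectivity: int

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def areas(self) -> np.ndarray:
        """Pixel count per region, index i -> region id i+1."""
        return np.bincount(self.labels.reshape(-1), minlength=self.n_regions + 1)[1:]


@dataclass(frozen=True)
class EdgeMap:
    """Sobel gradient magnitude plus its thresholded edge mask."""

    magnitude: np.ndarray
    mask: np.ndarray

    @property
    def n_edge_points(self) -> int:
        return int(self.mask.sum())


def median_filter(img: RasterImage, window: int = 5) -> RasterImage:
    """Median filter with a square window; despeckles salt-and-pepper noise."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if img.channels != 1:
        raise ValueError("median_filter expects a single-channel image")
    out = ndimage.median_filter(
        np.asarray(img.pixels, dtype=np.float64), size=window, mode="nearest"
    )
    return RasterImage(out, img.value_range)


def otsu_threshold(img: RasterImage) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit image.

    Returns the t in 0..254 maximizing the between-class variance
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))^2``, where class 0 holds pixels
    <= t.  Ties resolve to the smallest t.
    """
    if img.channels != 1:
        raise ValueError("otsu_threshold expects a single-channel image")
    px = np.asarray(img.pixels, dtype=np.float64)
    if img.value_range != RANGE_8BIT:
        px = px * 255.0
    vals = np.round(px).astype(np.int64).clip(0, 255)
    if np.all(vals == vals.reshape(-1)[0]):
        raise DegenerateImageError("constant image: Otsu threshold is undefined")
    hist = np.bincount(vals.reshape(-1), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]  # P(v <= t), t = 0..254
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * levels)[:-1]
    total_mean = float((p * levels).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, cum_mean / w0, 0.0)
        mu1 = np.where(w1 > 0, (total_mean - cum_mean) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(between))  # argmax -> first maximizer -> smallest t


def apply_threshold(img: RasterImage, t: float, foreground: str = "dark") -> BinaryMask:
    """Binarize at threshold t.

    ``foreground="dark"`` marks pixels <= t (holes image dark);
    ``foreground="bright"`` marks pixels > t.  The two masks are exact
    complements.
    """
    if foreground not in ("dark", "bright"):
        raise ValueError("foreground must be 'dark' or 'bright'")
    px = np.asarray(img.pixels, dtype=np.float64)
    if img.value_range != RANGE_8BIT:
        px = px * 255.0
    return BinaryMask(px <= t if foreground == "dark" else px > t)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_regions(mask: BinaryMask, connectivity: int = 8) -> LabeledRegions:
    """Connected-component labeling of the foreground under 4- or 8-adjacency.

    Region ids are assigned in raster-scan order of first encounter,
    starting at 1; 0 is background.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    return LabeledRegions(labels=labels, n_regions=int(n), connectivity=connectivity)


def remove_small_regions(regions: LabeledRegions, min_area: int = 5) -> LabeledRegions:
    """Drop regions smaller than ``min_area`` px and recompact ids to 1..n."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if regions.n_regions == 0 or min_area == 0:
        return regions
    areas = regions.areas()
    keep = np.flatnonzero(areas >= min_area) + 1  # surviving old ids, ascending
    remap = np.zeros(regions.n_regions + 1, dtype=regions.labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabeledRegions(
        labels=remap[regions.labels], n_regions=int(keep.size), connectivity=regions.connectivity
    )


def sobel_edges(img: RasterImage, edge_threshold: float = 0.2) -> EdgeMap:
    """3x3 Sobel gradient magnitude and its relative-threshold edge mask.

    Magnitude is ``sqrt(Gx^2 + Gy^2)`` of the standard smoothed derivative
    kernels; the mask keeps pixels with magnitude at least
    ``edge_threshold`` times the maximum.  A constant image has zero
    magnitude everywhere and, by convention, an empty mask.
    """
    if not 0.0 < edge_threshold <= 1.0:
        raise ValueError(f"edge_threshold must be in (0, 1], got {edge_threshold}")
    if img.channels != 1:
        raise ValueError("sobel_edges expects a single-channel image")
    px = np.asarray(img.pixels, dtype=np.float64)
    gx = ndimage.sobel(px, axis=1, mode="nearest")
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    mmax = mag.max()
    mask = np.zeros_like(mag, dtype=bool) if mmax == 0 else mag >= edge_threshold * mmax
    return EdgeMap(magnitude=mag, mask=mask)
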