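"""RGB to CIE L*a*b* conversion and pixel-feature extraction for clustering.

L*a*b* separates luminosity (L*, 0–100) from the two chromaticity axes
a* (green–red) and b* (blue–yellow), so the Euclidean distance between two
pixels approximates their perceived color difference.  Segmentation runs
K-means on a per-pixel feature matrix built from a configurable subset of
the three layers.

SEM micrographs are grayscale: once replicated into RGB and converted,
their chromaticity layers are identically zero.  Requesting purely
chromatic features on such an image would hand K-means a constant matrix,
so :func:`pixel_features` detects the degenerate case and falls back to
the luminosity layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import RANGE_8BIT, RasterImage

logger = logging.getLogger(__name__)

#: Chromaticity below this (on the a*/b* scale) counts as "no color signal".
EPSILON_CHROMA = 1e-3

_CHANNEL_INDEX = {"L": 0, "a": 1, "b": 2}


@dataclass(frozen=True)
class LabImage:
    """Per-pixel L* (luminosity), a* and b* (chromaticity) layers."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape) or self.L.ndim != 2:
            raise ValueError("L, a, b must be identically shaped 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def layer(self, name: str) -> np.ndarray:
        return (self.L, self.a, self.b)[_CHANNEL_INDEX[name]]


@dataclass(frozen=True)
class FeatureMatrix:
    """One feature vector per pixel, flattened row-major.

    ``shape_ref`` records the source (height, width) so cluster labels can
    be folded back into image coordinates.
    """

    X: np.ndarray
    channel_names: tuple[str, ...]
    shape_ref: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.shape_ref
        if self.X.ndim != 2 or self.X.shape[0] != h * w:
            raise ValueError(
                f"feature matrix rows {self.X.shape} inconsistent with image {self.shape_ref}"
            )
        if self.X.shape[1] != len(self.channel_names):
            raise ValueError("one column per channel name required")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# sRGB (IEC 61966-2-1) linear RGB -> CIE XYZ matrix, D65 white.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# Reference white taken as the image of (1, 1, 1) through the same matrix,
# so every gray pixel maps to exactly equal XYZ ratios and hence a* = b* = 0.
_WHITE = _RGB_TO_XYZ @ np.ones(3)
_DELTA = 6.0 / 29.0


def _srgb_gamma_expand(s: np.ndarray) -> np.ndarray:
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def rgb_to_lab(img: RasterImage) -> LabImage:
    """Convert an RGB image to CIE L*a*b* (sRGB primaries, D65 white).

    The chain is the standard sRGB gamma expansion to linear RGB, the
    linear map to CIE XYZ, and the CIE f-function transform to L*a*b*.
    The reference white is the sRGB matrix applied to unit RGB, which
    keeps gray pixels exactly achromatic (a* = b* = 0) — a property the
    grayscale-fallback logic in :func:`pixel_features` relies on.
    """
    if img.channels != 3:
        raise ValueError("rgb_to_lab expects a 3-channel image")
    px = np.asarray(img.pixels, dtype=np.float64)
    if img.value_range == RANGE_8BIT:
        px = px / 255.0
    xyz = _srgb_gamma_expand(px) @ _RGB_TO_XYZ.T
    f = _lab_f(xyz / _WHITE)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(L=L, a=a, b=b)


def delta_e(c1, c2) -> float:
    """Euclidean color difference between two L*a*b* triples."""
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    return float(np.sqrt(np.sum((c1 - c2) ** 2)))


def pixel_features(
    lab: LabImage,
    channels: str = "ab",
    standardize: bool = False,
    epsilon_chroma: float = EPSILON_CHROMA,
) -> FeatureMatrix:
    """Flatten selected L*a*b* layers into a per-pixel feature matrix.

    Parameters
    ----------
    channels
        Any non-empty combination of ``"L"``, ``"a"``, ``"b"``, e.g.
        ``"ab"``, ``"La"``, ``"Lab"``.  If all requested channels are
        chromatic but the image carries no chroma (max |a*|, |b*| below
        ``epsilon_chroma``), the selection falls back to ``"L"`` — this is
        what makes the pipeline work on grayscale SEM sources.
    standardize
        Optionally z-score each feature column (off by default; the
        clustering operates on raw L*a*b* units).
    """
    if not channels:
        raise ValueError("channel selection must be non-empty")
    names = tuple(channels)
    bad = [c for c in names if c not in _CHANNEL_INDEX]
    if bad:
        raise ValueError(f"unknown feature channel(s) {bad}; choose from L, a, b")

    chroma_only = all(c in ("a", "b") for c in names)
    if chroma_only:
        max_chroma = max(np.abs(lab.a).max(initial=0.0), np.abs(lab.b).max(initial=0.0))
        if max_chroma < epsilon_chroma:
            logger.info(
                "image is chromatically degenerate (max |a*|,|b*| = %.2g < %.2g); "
                "falling back to luminosity features",
                max_chroma,
                epsilon_chroma,
            )
            names = ("L",)

    cols = [lab.layer(c).reshape(-1) for c in names]
    X = np.column_stack(cols).astype(np.float64)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return FeatureMatrix(X=X, channel_names=names, shape_ref=lab.shape)
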