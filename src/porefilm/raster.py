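"""Image data model, PNG/TIFF I/O and grayscale pre-processing.

The pipeline works on a single carrier type, :class:`RasterImage`, which is
a thin validated wrapper around a numpy array plus an explicit declaration
of the value domain: 8-bit integer intensities (0–255) or normalized real
intensities (0–1).  Keeping the domain explicit avoids the classic
float/uint8 scaling bugs when images move between enhancement, color
conversion and thresholding stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import exposure

logger = logging.getLogger(__name__)

#: Declared pixel-value domains.
RANGE_8BIT = "0-255"
RANGE_UNIT = "0-1"


class RasterFormatError(ValueError):
    """Raised for unreadable, unsupported or malformed image files."""


@dataclass(frozen=True)
class RasterImage:
    """A 2-D grayscale or 3-channel RGB pixel grid.

    Parameters
    ----------
    pixels
        Array of shape ``(height, width)`` or ``(height, width, 3)``.
    value_range
        Either ``"0-255"`` (integer intensities) or ``"0-1"`` (real
        intensities produced by normalization).
    """

    pixels: np.ndarray
    value_range: str = RANGE_8BIT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"pixels must be (H, W) or (H, W, 3), got {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3 pixels, got {px.shape[:2]}")
        if self.value_range not in (RANGE_8BIT, RANGE_UNIT):
            raise ValueError(f"unknown value_range {self.value_range!r}")
        lo, hi = (0.0, 255.0) if self.value_range == RANGE_8BIT else (0.0, 1.0)
        pmin, pmax = float(px.min()), float(px.max())
        if pmin < lo - 1e-9 or pmax > hi + 1e-9:
            raise ValueError(
                f"pixel values [{pmin}, {pmax}] outside declared range {self.value_range}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean per-pixel mask; ``True`` marks foreground (hole) pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    def to_image(self, foreground_level: int = 0, background_level: int = 255) -> RasterImage:
        """Render the mask as an 8-bit image.

        By default foreground (holes) renders dark on a bright background,
        matching the appearance of pores in SEM surface micrographs.
        """
        out = np.where(self.values, foreground_level, background_level).astype(np.uint8)
        return RasterImage(out, RANGE_8BIT)


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG or TIFF file into an 8-bit :class:`RasterImage`.

    Palette images are expanded, alpha channels stripped, and 16-bit data
    linearly rescaled to 0–255 so the rest of the pipeline has a single
    internal depth.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.width == 0 or im.height == 0:
                raise RasterFormatError(f"zero-area image: {path}")
            mode = im.mode
            if mode == "P":
                im = im.convert("RGB")
            elif mode in ("RGBA", "LA", "PA"):
                im = im.convert("RGB" if mode == "RGBA" else "L")
            elif mode in ("I", "I;16", "I;16B", "I;16L"):
                arr16 = np.asarray(im.convert("I"), dtype=np.float64)
                arr = np.round(arr16 / 65535.0 * 255.0)
                return RasterImage(arr.astype(np.uint8), RANGE_8BIT)
            elif mode not in ("L", "RGB"):
                raise RasterFormatError(f"unsupported image mode {mode!r}: {path}")
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise RasterFormatError(f"cannot read image file: {path}") from exc
    except UnidentifiedImageError as exc:
        raise RasterFormatError(f"not a recognized raster format: {path}") from exc
    return RasterImage(arr.astype(np.uint8), RANGE_8BIT)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write an image losslessly as PNG or TIFF (chosen by extension).

    Unit-range images are scaled to 0–255 before encoding, since the
    on-disk container is 8-bit; re-reading such a file therefore yields the
    scaled 8-bit values.
    """
    path = Path(path)
    px = img.pixels
    if img.value_range == RANGE_UNIT:
        px = np.round(np.asarray(px, dtype=np.float64) * 255.0)
    arr = np.round(np.asarray(px, dtype=np.float64)).clip(0, 255).astype(np.uint8)
    try:
        Image.fromarray(arr).save(path)
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Serialize a mask as a 0/255 grayscale PNG (foreground = 255)."""
    write_image(RasterImage(np.where(mask.values, 255, 0).astype(np.uint8)), path)


def to_rgb(img: RasterImage) -> RasterImage:
    """Replicate a grayscale image into three channels; RGB passes through."""
    if img.channels == 3:
        return img
    return RasterImage(np.repeat(img.pixels[:, :, None], 3, axis=2), img.value_range)


def to_gray(img: RasterImage) -> RasterImage:
    """Collapse to single-channel 0–255 (ITU-R 601 luma for RGB input)."""
    if img.channels == 1:
        px = img.pixels
        if img.value_range == RANGE_UNIT:
            px = np.round(px * 255.0)
        return RasterImage(np.asarray(px, dtype=np.float64).round().astype(np.uint8))
    w = np.array([0.299, 0.587, 0.114])
    px = np.asarray(img.pixels, dtype=np.float64)
    if img.value_range == RANGE_UNIT:
        px = px * 255.0
    return RasterImage(np.round(px @ w).clip(0, 255).astype(np.uint8))


def normalize_intensity(
    img: RasterImage, low_pct: float = 1.0, high_pct: float = 99.0
) -> RasterImage:
    """Clip extreme pixels at percentile bounds and rescale to [0, 1].

    Pixels below the ``low_pct`` percentile or above the ``high_pct``
    percentile are saturated, then the clip bounds are affinely mapped onto
    0 and 1.  A constant image has no usable spread; it maps to all zeros
    and a warning is logged so batch runs survive blank frames.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    px = np.asarray(img.pixels, dtype=np.float64)
    lo = np.percentile(px, low_pct)
    hi = np.percentile(px, high_pct)
    if hi <= lo:
        logger.warning(
            "degenerate input: percentile clip bounds coincide (%.4g); returning all-zero image",
            lo,
        )
        return RasterImage(np.zeros_like(px), RANGE_UNIT)
    out = (np.clip(px, lo, hi) - lo) / (hi - lo)
    return RasterImage(out, RANGE_UNIT)


def equalize_hist(img: RasterImage) -> RasterImage:
    """Cumulative-histogram equalization over 256 bins, output 0–255."""
    if img.channels != 1:
        raise ValueError("equalize_hist expects a single-channel image")
    px = img.pixels
    if img.value_range == RANGE_UNIT:
        px = np.round(np.asarray(px, dtype=np.float64) * 255.0).astype(np.uint8)
    eq = exposure.equalize_hist(np.asarray(px, dtype=np.uint8), nbins=256)
    return RasterImage(np.round(eq * 255.0).astype(np.uint8), RANGE_8BIT)


def invert(img: RasterImage) -> RasterImage:
    """Inverse grey level: v -> 255 - v."""
    if img.channels != 1:
        raise ValueError("invert expects a single-channel image")
    if img.value_range != RANGE_8BIT:
        raise ValueError("invert expects a 0-255 image")
    px = np.asarray(img.pixels, dtype=np.float64)
    return RasterImage(255.0 - px, RANGE_8BIT)
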