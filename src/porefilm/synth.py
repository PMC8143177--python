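"""Synthetic SEM-like film micrographs and fruit frames with ground truth.

No public micrograph data accompanies the film-porosity problem, so the
generators here emulate the relevant image structure: a bright, smoothly
textured film surface punctured by dark quasi-elliptical pores (films),
and a bright textured disk on a dark background (fruit frames).  Both
carry exact rasterized ground truth, which is what makes recovery of the
planted porosity testable.

Rasterization rule: a pixel belongs to a hole/fruit iff its integer
center satisfies the ellipse inequality, so ground-truth areas are exact
integer pixel counts.  Noise is added last: zero-mean Gaussian intensity
noise clipped to range, then salt-and-pepper impulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RANGE_8BIT, RasterImage


class CapacityError(RuntimeError):
    """Raised when the requested holes cannot be placed without overlap."""


@dataclass(frozen=True)
class HoleTruth:
    center: tuple[int, int]  # (row, col)
    radii: tuple[float, float]  # (row_radius, col_radius)
    area: int  # rasterized pixel count


@dataclass(frozen=True)
class GroundTruth:
    holes: tuple[HoleTruth, ...]
    total_area: int
    true_percent_area: float


@dataclass(frozen=True)
class FilmSpec:
    """Parameters of one synthetic film micrograph.

    Defaults describe a plausible SEM film surface at small scale: a
    bright film (level 200) with gentle low-frequency texture, dark pores
    (level 30), Gaussian read noise of sigma 8 intensity units and 1%
    salt-and-pepper impulses.
    """

    width: int = 200
    height: int = 200
    n_holes: int = 10
    radius_range: tuple[float, float] = (4.0, 10.0)
    ellipticity_range: tuple[float, float] = (1.0, 1.5)
    background_level: int = 200
    hole_level: int = 30
    texture_amplitude: float = 10.0
    gaussian_sigma: float = 8.0
    impulse_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hole_level >= self.background_level:
            raise ValueError("holes must be darker than the background")
        if self.radius_range[0] < 2:
            raise ValueError("hole radii must be >= 2 px")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max)")
        if self.ellipticity_range[0] < 1.0:
            raise ValueError("ellipticity factors start at 1.0 (circular)")
        if not 0.0 <= self.impulse_fraction <= 1.0:
            raise ValueError("impulse_fraction must lie in [0, 1]")


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[int, int], radii: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _texture(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency texture: two random-phase sinusoid products."""
    if amplitude == 0:
        return np.zeros(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    h, w = shape
    tex = np.zeros(shape)
    for _ in range(2):
        fr, fc = rng.uniform(0.5, 2.0, size=2)  # cycles per image side
        pr, pc = rng.uniform(0, 2 * np.pi, size=2)
        tex += np.sin(2 * np.pi * fr * rr / h + pr) * np.sin(2 * np.pi * fc * cc / w + pc)
    tex *= amplitude / max(np.abs(tex).max(), 1e-12)
    return tex


def add_noise(
    img: RasterImage, gaussian_sigma: float, impulse_fraction: float, seed: int
) -> RasterImage:
    """Add clipped Gaussian noise, then salt-and-pepper impulses.

    Impulses set a ``impulse_fraction`` of pixels (drawn without
    replacement) to 0 or 255 with equal probability.
    """
    if not 0.0 <= impulse_fraction <= 1.0:
        raise ValueError("impulse_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x401)))
    px = np.asarray(img.pixels, dtype=np.float64)
    scale = 255.0 if img.value_range == RANGE_8BIT else 1.0
    if gaussian_sigma > 0:
        px = np.clip(px + rng.normal(0.0, gaussian_sigma, size=px.shape), 0.0, scale)
    if impulse_fraction > 0:
        n = px.shape[0] * px.shape[1]
        n_imp = int(round(impulse_fraction * n))
        flat_idx = rng.choice(n, size=n_imp, replace=False)
        salt = rng.random(n_imp) < 0.5
        flat = px.reshape(n, -1) if px.ndim == 3 else px.reshape(n)
        if px.ndim == 3:
            flat[flat_idx] = np.where(salt[:, None], scale, 0.0)
        else:
            flat[flat_idx] = np.where(salt, scale, 0.0)
        px = flat.reshape(px.shape)
    return RasterImage(px, img.value_range)


def generate_film(spec: FilmSpec) -> tuple[RasterImage, GroundTruth]:
    """Render a synthetic film micrograph and its exact pore ground truth.

    Hole centers are drawn by rejection sampling until pairwise
    non-overlapping (with a three-pixel guard gap) and fully inside the
    frame; more than 10,000 failed draws raise :class:`CapacityError`.
    Identical specs (including seed) render bit-identical images.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xF11A)))
    shape = (spec.height, spec.width)
    base = spec.background_level + _texture(shape, spec.texture_amplitude, rng)
    base = np.clip(base, 0.0, 255.0)

    holes: list[HoleTruth] = []
    placed: list[tuple[int, int, float]] = []  # (row, col, bounding radius)
    attempts = 0
    while len(holes) < spec.n_holes:
        if attempts >= 10_000:
            raise CapacityError(
                f"could not place {spec.n_holes} holes in {spec.width}x{spec.height} "
                f"after {attempts} attempts"
            )
        attempts += 1
        r_minor = rng.uniform(*spec.radius_range)
        ell = rng.uniform(*spec.ellipticity_range)
        rr, rc = (r_minor * ell, r_minor) if rng.random() < 0.5 else (r_minor, r_minor * ell)
        rmax = max(rr, rc)
        margin = int(np.ceil(rmax)) + 1
        if 2 * margin >= min(shape):
            continue
        cy = int(rng.integers(margin, spec.height - margin))
        cx = int(rng.integers(margin, spec.width - margin))
        # 3 px guard gap keeps distinct pores from touching even diagonally
        if any(np.hypot(cy - py, cx - px_) <= rmax + pr + 3.0 for py, px_, pr in placed):
            continue
        mask = _ellipse_mask(shape, (cy, cx), (rr, rc))
        holes.append(HoleTruth(center=(cy, cx), radii=(rr, rc), area=int(mask.sum())))
        placed.append((cy, cx, rmax))
        base[mask] = spec.hole_level

    img = RasterImage(base, RANGE_8BIT)
    img = add_noise(img, spec.gaussian_sigma, spec.impulse_fraction, spec.seed)
    total = sum(h.area for h in holes)
    truth = GroundTruth(
        holes=tuple(holes),
        total_area=total,
        true_percent_area=100.0 * total / (spec.width * spec.height),
    )
    return img, truth


def generate_fruit(
    width: int,
    height: int,
    radius: float,
    seed: int = 0,
    fruit_level: int = 200,
    background_level: int = 20,
    texture_amplitude: float = 10.0,
    gaussian_sigma: float = 0.0,
    impulse_fraction: float = 0.0,
) -> tuple[RasterImage, GroundTruth]:
    """Render a bright textured disk (the fruit) on a dark background."""
    if radius >= min(width, height) / 2:
        raise ValueError("fruit radius must fit inside the frame")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF007)))
    shape = (height, width)
    base = np.full(shape, float(background_level))
    center = (height // 2, width // 2)
    mask = _ellipse_mask(shape, center, (radius, radius))
    tex = _texture(shape, texture_amplitude, rng)
    base[mask] = np.clip(fruit_level + tex[mask], 0.0, 255.0)
    img = RasterImage(base, RANGE_8BIT)
    img = add_noise(img, gaussian_sigma, impulse_fraction, seed)
    area = int(mask.sum())
    truth = GroundTruth(
        holes=(HoleTruth(center=center, radii=(radius, radius), area=area),),
        total_area=area,
        true_percent_area=100.0 * area / (width * height),
    )
    return img, truth
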