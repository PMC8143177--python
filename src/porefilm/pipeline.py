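"""End-to-end orchestration of the segmentation chain.

Film pipeline: read -> RGB -> percentile normalization -> L*a*b* ->
pixel features -> (elbow scan if K is automatic) -> K-means -> hole
cluster by darkness -> median despeckle -> Otsu binarization -> small
region removal -> connected components -> region morphometry -> porosity
summary.

Fruit pipeline: grey-level inversion -> Sobel edges -> Otsu segmentation
-> largest-region summary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import raster, colorspace, clustering, segmentation, characterization
from .raster import BinaryMask, RasterImage
from .characterization import FilmSummary, FruitSummary, RegionRecord

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the pipeline and cause."""


@dataclass
class PipelineConfig:
    """All tunables of the film and fruit pipelines.

    ``k="auto"`` selects K by the elbow scan over ``k_range``; an integer
    fixes it (K=2 separates holes from background on film micrographs).
    ``median_size`` below 3 skips the despeckling stage entirely, which
    is appropriate for noise-free input since the median filter biases
    hole boundaries by design.  ``otsu_on`` chooses whether the threshold
    adapts to the hole-cluster rendering (default) or the full grayscale
    image.
    """

    channels: str = "ab"
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 6)
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    elbow_subsample: int | None = 50_000
    low_pct: float = 1.0
    high_pct: float = 99.0
    median_size: int = 5
    min_area: int = 5
    connectivity: int = 8
    edge_threshold: float = 0.2
    foreground: str = "dark"
    otsu_on: str = "hole_mask"  # or "image"
    save_intermediates: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.k, str) and self.k != "auto":
            self.k = int(self.k)
        if self.otsu_on not in ("hole_mask", "image"):
            raise ValueError("otsu_on must be 'hole_mask' or 'image'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)


@dataclass
class FilmResult:
    summary: FilmSummary
    records: list[RegionRecord]
    artifacts: dict = field(default_factory=dict)


@dataclass
class FruitResult:
    summary: FruitSummary
    artifacts: dict = field(default_factory=dict)


def _stage(name: str, t0: float, **params) -> float:
    t1 = time.perf_counter()
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage %-16s %6.1f ms  %s", name, (t1 - t0) * 1e3, kv)
    return t1


def _load(image: str | Path | RasterImage) -> RasterImage:
    return image if isinstance(image, RasterImage) else raster.read_image(image)


def run_pipeline(
    image: str | Path | RasterImage, config: PipelineConfig | None = None
) -> FilmResult:
    """Run the full film-porosity chain on one image.

    Returns the porosity summary, per-region records and a dictionary of
    intermediate artifacts (elbow scan, cluster result, masks, label
    image) for inspection or saving.
    """
    config = config or PipelineConfig()
    art: dict = {}
    t0 = time.perf_counter()
    try:
        img = _load(image)
        gray_ref = raster.to_gray(img)  # original intensities, for hole choice & mean_gray
        t0 = _stage("read", t0, shape=img.shape, channels=img.channels)

        rgb = raster.to_rgb(img)
        norm = raster.normalize_intensity(rgb, config.low_pct, config.high_pct)
        t0 = _stage("normalize", t0, pct=(config.low_pct, config.high_pct))

        lab = colorspace.rgb_to_lab(norm)
        feats = colorspace.pixel_features(lab, channels=config.channels)
        t0 = _stage("features", t0, channels="".join(feats.channel_names))

        if config.k == "auto":
            scan = clustering.elbow_scan(
                feats,
                k_min=config.k_range[0],
                k_max=config.k_range[1],
                max_iter=config.max_iter,
                tol=config.tol,
                seed=config.seed,
                n_init=config.n_init,
                subsample=config.elbow_subsample,
            )
            k = scan.selected_k
            art["elbow"] = scan
            t0 = _stage("elbow", t0, selected_k=k, wcss=[round(w, 1) for w in scan.wcss_values])
        else:
            k = int(config.k)

        km = clustering.kmeans_fit(
            feats, k, max_iter=config.max_iter, tol=config.tol,
            seed=config.seed, n_init=config.n_init,
        )
        art["kmeans"] = km
        label_img = clustering.labels_to_image(km)
        masks = clustering.cluster_masks(label_img)
        hole = clustering.select_hole_cluster(masks, gray_ref)
        art["cluster_masks"], art["hole_mask_raw"] = masks, hole
        t0 = _stage("kmeans", t0, k=k, wcss=round(km.wcss, 2), iters=km.iterations)

        # holes render dark on bright background, as in the source images
        rendered = hole.to_image(foreground_level=0, background_level=255)
        if config.median_size >= 3:
            rendered = segmentation.median_filter(rendered, config.median_size)
        otsu_src = gray_ref if config.otsu_on == "image" else rendered
        t = segmentation.otsu_threshold(otsu_src)
        mask = segmentation.apply_threshold(rendered, t, foreground=config.foreground)
        t0 = _stage("binarize", t0, median=config.median_size, otsu_t=t)

        regions = segmentation.label_regions(mask, config.connectivity)
        regions = segmentation.remove_small_regions(regions, config.min_area)
        art["hole_mask"], art["regions"] = mask, regions
        t0 = _stage("regions", t0, n=regions.n_regions, min_area=config.min_area)

        records = characterization.region_metrics(regions, gray_ref)
        summary = characterization.film_summary(records, img.width * img.height)
        _stage("summary", t0, regions=summary.region_number,
               percent_area=round(summary.percent_area, 3))
    except Exception as exc:
        raise PipelineError(f"film pipeline failed: {exc}") from exc
    return FilmResult(summary=summary, records=records, artifacts=art)


def run_fruit_pipeline(
    image: str | Path | RasterImage,
    config: PipelineConfig | None = None,
    edge_color: str = "",
) -> FruitResult:
    """Segment a fruit frame and summarize its largest region.

    The frame is inverted (fruit becomes dark), Sobel edges extracted,
    Otsu applied to the inverted image, and the largest connected region
    reported with its boundary-band edge-point count.
    """
    config = config or PipelineConfig()
    art: dict = {}
    try:
        img = _load(image)
        gray = raster.to_gray(img)
        inv = raster.invert(gray)
        edges = segmentation.sobel_edges(inv, config.edge_threshold)
        t = segmentation.otsu_threshold(inv)
        mask = segmentation.apply_threshold(inv, t, foreground="dark")
        regions = segmentation.label_regions(mask, config.connectivity)
        regions = segmentation.remove_small_regions(regions, config.min_area)
        if regions.n_regions == 0:
            raise ValueError("no fruit region found")
        summary = characterization.fruit_summary(regions, edges, edge_color=edge_color)
        art.update(inverse=inv, edges=edges, mask=mask, regions=regions)
    except Exception as exc:
        raise PipelineError(f"fruit pipeline failed: {exc}") from exc
    return FruitResult(summary=summary, artifacts=art)


def save_intermediates(result: FilmResult | FruitResult, out_dir: str | Path) -> None:
    """Dump intermediate masks/edge maps of a run as PNGs and CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = result.artifacts
    if "hole_mask_raw" in art:
        raster.write_mask(art["hole_mask_raw"], out / "hole_cluster_raw.png")
    if "hole_mask" in art:
        raster.write_mask(art["hole_mask"], out / "hole_mask.png")
    if "regions" in art:
        lab = art["regions"].labels
        scale = 255 // max(art["regions"].n_regions, 1)
        raster.write_image(
            RasterImage(np.clip(lab * scale, 0, 255).astype(np.uint8)), out / "regions.png"
        )
    if "elbow" in art:
        scan = art["elbow"]
        lines = ["k,wcss"] + [f"{k},{w}" for k, w in zip(scan.k_values, scan.wcss_values)]
        (out / "elbow.csv").write_text("\n".join(lines) + "\n")
    if "edges" in art:
        raster.write_mask(BinaryMask(art["edges"].mask), out / "edges.png")
    if "inverse" in art:
        raster.write_image(art["inverse"], out / "inverse.png")
    if "mask" in art:
        raster.write_mask(art["mask"], out / "mask.png")
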