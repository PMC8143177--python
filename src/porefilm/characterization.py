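"""Per-region morphometry and the film / fruit summary tables.

Per region the module reports area, perimeter, centroid, bounding box and
mean original grayscale.  Perimeter follows the boundary-chain convention:
the closed 8-connected chain of boundary pixel centers, axial steps
counted as 1 and diagonal steps as sqrt(2).  Film summaries aggregate the
regions into (region number, total area, % area, average region size) —
the porosity readout used to rank film formulations; fruit summaries
report the largest region's area, perimeter and boundary edge-point
count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterImage
from .segmentation import EdgeMap, LabeledRegions

_SQRT2 = float(np.sqrt(2.0))

# Moore neighborhood in clockwise order starting from West.
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class RegionRecord:
    region_id: int
    area: int
    perimeter: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive
    mean_gray: float


@dataclass(frozen=True)
class FilmSummary:
    """Porosity roll-up of one film micrograph."""

    region_number: int
    total_area: int
    percent_area: float
    average_area_size: float

    @classmethod
    def from_counts(cls, region_number: int, total_area: int, image_area: int) -> "FilmSummary":
        """Build a summary directly from aggregate counts."""
        if image_area <= 0:
            raise ValueError("image_area must be positive")
        if region_number == 0:
            return cls(0, 0, 0.0, 0.0)
        return cls(
            region_number=region_number,
            total_area=total_area,
            percent_area=100.0 * total_area / image_area,
            average_area_size=total_area / region_number,
        )


@dataclass(frozen=True)
class FruitSummary:
    """Largest-region roll-up of one fruit image."""

    area: int
    perimeter: float
    n_edge_points: int
    edge_color: str = ""


def boundary_chain_perimeter(mask: np.ndarray) -> float:
    """Length of the closed boundary chain of a single connected region.

    The outer boundary is traced with Moore-neighbor following; the chain
    length sums unit axial and sqrt(2) diagonal steps between consecutive
    boundary pixel centers.  A single pixel has no chain; its perimeter is
    1.0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region")
    if rows.size == 1:
        return 1.0
    # pad so neighbor lookups never leave the array
    padded = np.pad(mask, 1)
    start = (int(rows[0]) + 1, int(cols[0]) + 1)  # raster-first pixel; its W neighbor is bg

    def neighbor(p, d):
        return (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])

    # trace until a (pixel, backtrack-direction) state repeats, then measure
    # the cycle between the two occurrences of that state
    states: list[tuple[tuple[int, int], int]] = [(start, 0)]
    seen = {states[0]: 0}
    cur, back = start, 0
    max_steps = 8 * rows.size + 16
    for _ in range(max_steps):
        nxt = None
        for i in range(1, 9):
            d = (back + i) % 8
            cand = neighbor(cur, d)
            if padded[cand]:
                prev_bg = neighbor(cur, (back + i - 1) % 8) if i > 1 else neighbor(cur, back)
                dr, dc = prev_bg[0] - cand[0], prev_bg[1] - cand[1]
                nxt, nback = cand, _MOORE.index((dr, dc))
                break
        if nxt is None:  # isolated pixel (cannot happen for size > 1 connected region)
            return 1.0
        state = (nxt, nback)
        if state in seen:
            cycle = [s[0] for s in states[seen[state]:]] + [nxt]
            return float(
                sum(
                    1.0 if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1 else _SQRT2
                    for a, b in zip(cycle, cycle[1:])
                )
            )
        seen[state] = len(states)
        states.append(state)
        cur, back = nxt, nback
    raise RuntimeError("boundary trace failed to close")  # pragma: no cover


def region_metrics(regions: LabeledRegions, gray: RasterImage) -> list[RegionRecord]:
    """Compute one :class:`RegionRecord` per labeled region.

    ``gray`` should be the original (pre-filter) grayscale image so the
    per-region mean intensity reflects the source data.
    """
    if gray.shape != regions.shape:
        raise ValueError(f"gray image {gray.shape} does not match label image {regions.shape}")
    g = np.asarray(gray.pixels, dtype=np.float64)
    records: list[RegionRecord] = []
    if regions.n_regions == 0:
        return records
    ids = np.arange(1, regions.n_regions + 1)
    areas = regions.areas()
    centroids = ndimage.center_of_mass(np.ones_like(g), regions.labels, ids)
    means = ndimage.mean(g, regions.labels, ids)
    slices = ndimage.find_objects(regions.labels)
    for rid, area, cen, mg, sl in zip(ids, areas, centroids, means, slices):
        sub = regions.labels[sl] == rid
        records.append(
            RegionRecord(
                region_id=int(rid),
                area=int(area),
                perimeter=boundary_chain_perimeter(sub),
                centroid=(float(cen[0]), float(cen[1])),
                bbox=(sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1),
                mean_gray=float(mg),
            )
        )
    return records


def film_summary(records: list[RegionRecord], image_area: int) -> FilmSummary:
    """Aggregate region records into the porosity summary of one film."""
    total = sum(r.area for r in records)
    return FilmSummary.from_counts(len(records), total, image_area)


def fruit_summary(
    regions: LabeledRegions, edges: EdgeMap, edge_color: str = ""
) -> FruitSummary:
    """Summarize the largest region (the fruit) of a segmented frame.

    The edge-point count is the number of Sobel edge pixels falling in the
    fruit's boundary band (the one-pixel region boundary dilated by one).
    """
    if regions.n_regions == 0:
        raise ValueError("no regions found: nothing to summarize")
    areas = regions.areas()
    rid = int(np.argmax(areas)) + 1  # ties -> lowest id
    mask = regions.region_mask(rid)
    boundary = mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    band = ndimage.binary_dilation(boundary, structure=np.ones((3, 3), bool))
    n_edge = int(np.count_nonzero(edges.mask & band))
    return FruitSummary(
        area=int(areas[rid - 1]),
        perimeter=boundary_chain_perimeter(mask),
        n_edge_points=n_edge,
        edge_color=edge_color,
    )


FILM_COLUMNS = ["sample", "region_number", "total_area", "percent_area", "average_area_size"]
FRUIT_COLUMNS = ["sample", "area_pixels", "perimeter", "n_edge_points"]


def export_tables(
    summaries: dict[str, FilmSummary | FruitSummary], path: str | Path
) -> None:
    """Write a named collection of summaries as CSV plus a JSON mirror.

    ``path`` is the CSV destination; the JSON mirror lands next to it with
    a ``.json`` suffix.  Film and fruit summaries may not be mixed in one
    table.
    """
    if not summaries:
        raise ValueError("no summaries to export")
    kinds = {type(s) for s in summaries.values()}
    if len(kinds) != 1:
        raise ValueError("cannot mix film and fruit summaries in one table")
    path = Path(path)
    rows = []
    if kinds == {FilmSummary}:
        for name, s in summaries.items():
            rows.append(
                {
                    "sample": name,
                    "region_number": s.region_number,
                    "total_area": s.total_area,
                    "percent_area": round(s.percent_area, 2),
                    "average_area_size": round(s.average_area_size, 2),
                }
            )
        df = pd.DataFrame(rows, columns=FILM_COLUMNS)
    else:
        for name, s in summaries.items():
            rows.append(
                {
                    "sample": name,
                    "area_pixels": s.area,
                    "perimeter": round(s.perimeter, 2),
                    "n_edge_points": s.n_edge_points,
                }
            )
        df = pd.DataFrame(rows, columns=FRUIT_COLUMNS)
    df.to_csv(path, index=False)
    mirror = {name: asdict(s) for name, s in summaries.items()}
    path.with_suffix(".json").write_text(json.dumps(mirror, indent=2))
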