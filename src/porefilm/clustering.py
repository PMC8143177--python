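"""K-means pixel classification with elbow-based automatic cluster count.

The clustering engine is Lloyd's algorithm with greedy k-means++ seeding,
seeded restarts, and a Hartigan-style single-point refinement after
convergence; the automatic choice of K scans a candidate range,
records the within-cluster sum of squares (WCSS) per K, and places the
"knee" of the curve at the point of maximum perpendicular distance to the
chord joining its endpoints after min-max normalization of both axes.

Lloyd's is implemented here rather than delegated so that the per-iteration
WCSS trace, the deterministic empty-cluster reseeding rule and the restart
bookkeeping — all of which the surrounding pipeline and its tests rely on —
are explicit and inspectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import BinaryMask, RasterImage
from .colorspace import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMeansResult:
    """Outcome of one K-means fit (best of the seeded restarts)."""

    k: int
    centroids: np.ndarray  # (k, n_features)
    labels: np.ndarray  # (n_pixels,) ints in [0, k)
    wcss: float
    wcss_history: tuple[float, ...]  # per-Lloyd-iteration objective, non-increasing
    iterations: int
    converged: bool
    shape_ref: tuple[int, int] | None = None


@dataclass(frozen=True)
class ElbowScan:
    """WCSS-vs-K curve and the automatically selected cluster count."""

    k_values: tuple[int, ...]
    wcss_values: tuple[float, ...]
    selected_k: int


def _wcss(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean distances, (n, k); ties go to the lowest index
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding.

    Each new centroid is drawn by D^2 sampling; among ``2 + log(k)``
    candidate draws the one minimizing the resulting potential is kept —
    the standard hardened variant of k-means++.
    """
    n = X.shape[0]
    n_trials = 2 + int(np.log(k)) if k > 1 else 1
    centroids = np.empty((k, X.shape[1]), dtype=np.float64)
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)  # all points coincide with a chosen centroid
            centroids[j] = X[idx]
            d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
            continue
        cand_idx = rng.choice(n, size=n_trials, p=d2 / total)
        cand_d2 = np.minimum(d2[None, :], ((X[None, :, :] - X[cand_idx, None, :]) ** 2).sum(axis=2))
        best = int(np.argmin(cand_d2.sum(axis=1)))
        centroids[j] = X[cand_idx[best]]
        d2 = cand_d2[best]
    return centroids


def _hartigan_polish(
    X: np.ndarray, centroids: np.ndarray, labels: np.ndarray, max_moves: int = 1000
) -> tuple[np.ndarray, np.ndarray, int]:
    """First-variation refinement of a converged Lloyd solution.

    Repeatedly applies the single best point-to-cluster move while any
    move strictly lowers the objective, using the exact size-weighted
    change formula ``n_t/(n_t+1) d(x,c_t)^2 - n_s/(n_s-1) d(x,c_s)^2``.
    Lloyd fixed points need not be stationary under single-point moves,
    so this escapes a class of local minima that restarts alone hit.
    """
    k = centroids.shape[0]
    labels = labels.copy()
    centroids = centroids.copy()
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    n = X.shape[0]
    moves = 0
    while moves < max_moves:
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        own = d2[np.arange(n), labels]
        cs = counts[labels]
        removable = cs > 1  # a singleton cluster may not be emptied
        remove = cs / np.maximum(cs - 1.0, 1.0) * own
        add = counts[None, :] / (counts[None, :] + 1.0) * d2
        delta = add - remove[:, None]
        delta[np.arange(n), labels] = np.inf
        delta[~removable, :] = np.inf
        i, t = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, t] >= -1e-10:
            break
        s = labels[i]
        centroids[s] = (counts[s] * centroids[s] - X[i]) / (counts[s] - 1.0)
        centroids[t] = (counts[t] * centroids[t] + X[i]) / (counts[t] + 1.0)
        counts[s] -= 1.0
        counts[t] += 1.0
        labels[i] = t
        moves += 1
    return centroids, labels, moves


def _lloyd(
    X: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    centroids = _kmeanspp_init(X, k, rng)
    history: list[float] = []
    converged = False
    labels = _assign(X, centroids)
    for it in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centroids[j] = X[members].mean(axis=0)
            else:
                # deterministic rescue: reseed from the point farthest
                # from its current centroid
                far = ((X - centroids[labels]) ** 2).sum(axis=1).argmax()
                new_centroids[j] = X[far]
        labels = _assign(X, new_centroids)
        history.append(_wcss(X, new_centroids, labels))
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    return centroids, labels, history, it, converged


def kmeans_fit(
    features: FeatureMatrix | np.ndarray,
    k: int,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
    n_init: int = 10,
) -> KMeansResult:
    """Fit K-means by Lloyd's algorithm, returning the best of ``n_init`` restarts.

    Each restart draws fresh k-means++ centroids from a seeded stream;
    iteration stops when the maximum centroid displacement drops below
    ``tol`` or ``max_iter`` is reached.  The restart with the lowest final
    WCSS wins.
    """
    shape_ref = None
    if isinstance(features, FeatureMatrix):
        shape_ref = features.shape_ref
        X = features.X
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_points, got k={k} for n={n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    best = None
    streams = np.random.SeedSequence(seed).spawn(n_init)
    for ss in streams:
        rng = np.random.default_rng(ss)
        centroids, labels, history, iters, converged = _lloyd(X, k, max_iter, tol, rng)
        centroids, labels, moves = _hartigan_polish(X, centroids, labels)
        if moves:
            history.append(_wcss(X, centroids, labels))
        wcss = history[-1] if history else _wcss(X, centroids, labels)
        if best is None or wcss < best[0] - 1e-12:
            best = (wcss, centroids, labels, history, iters, converged)
    wcss, centroids, labels, history, iters, converged = best
    return KMeansResult(
        k=k,
        centroids=centroids,
        labels=labels,
        wcss=wcss,
        wcss_history=tuple(history),
        iterations=iters,
        converged=converged,
        shape_ref=shape_ref,
    )


def select_k(k_values, wcss_values) -> int:
    """Locate the knee of a WCSS-vs-K curve.

    Both axes are min-max normalized to [0, 1]; the knee is the K whose
    curve point lies farthest (perpendicular distance) from the chord
    joining the first and last points.  Ties — including a perfectly
    linear or flat decline, where every distance is zero — resolve to the
    smallest K.
    """
    ks = np.asarray(k_values, dtype=np.float64)
    ws = np.asarray(wcss_values, dtype=np.float64)
    if ks.size != ws.size:
        raise ValueError("k_values and wcss_values must have equal length")
    if ks.size < 3:
        raise ValueError("knee detection needs at least 3 curve points")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    wspan = ws.max() - ws.min()
    y = (ws - ws.min()) / wspan if wspan > 0 else np.zeros_like(ws)
    # perpendicular distance to the chord (x0,y0)-(x1,y1)
    vx, vy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(vx, vy)
    dist = np.abs(vx * (y - y[0]) - vy * (x - x[0])) / norm
    dist[dist < 1e-9] = 0.0  # snap float noise so exact ties resolve by the tie rule
    best = int(np.argmax(dist))  # argmax returns the first (smallest-K) maximizer
    return int(k_values[best])


def elbow_scan(
    features: FeatureMatrix | np.ndarray,
    k_min: int = 2,
    k_max: int = 6,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
    n_init: int = 10,
    subsample: int | None = None,
) -> ElbowScan:
    """Scan K over [k_min, k_max] and pick the elbow of the WCSS curve.

    ``subsample`` optionally caps the number of pixels used during the
    scan (a seeded uniform draw); the final segmentation fit always runs
    on all pixels.
    """
    if not 1 <= k_min < k_max:
        raise ValueError(f"need 1 <= k_min < k_max, got ({k_min}, {k_max})")
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    if k_max > X.shape[0]:
        raise ValueError("k_max exceeds number of points")
    if subsample is not None and subsample < X.shape[0]:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE1B0)))
        X = X[rng.choice(X.shape[0], size=subsample, replace=False)]
    ks = list(range(k_min, k_max + 1))
    wcss = []
    for k in ks:
        res = kmeans_fit(X, k, max_iter=max_iter, tol=tol, seed=seed + k, n_init=n_init)
        wcss.append(res.wcss)
    for i in range(1, len(wcss)):
        if wcss[i] > wcss[i - 1] + 1e-9:
            logger.warning(
                "best-of-restarts WCSS increased from k=%d (%.4g) to k=%d (%.4g)",
                ks[i - 1], wcss[i - 1], ks[i], wcss[i],
            )
    return ElbowScan(
        k_values=tuple(ks), wcss_values=tuple(wcss), selected_k=select_k(ks, wcss)
    )


def labels_to_image(result: KMeansResult, shape_ref: tuple[int, int] | None = None) -> np.ndarray:
    """Fold the flat label vector back into a (height, width) label image."""
    shape = shape_ref or result.shape_ref
    if shape is None:
        raise ValueError("no shape_ref available to fold labels into")
    h, w = shape
    if result.labels.size != h * w:
        raise ValueError(f"{result.labels.size} labels cannot fill a {h}x{w} image")
    return result.labels.reshape(h, w)


def cluster_masks(label_img: np.ndarray) -> list[BinaryMask]:
    """One boolean mask per distinct cluster label (ascending label order).

    The masks are pairwise disjoint and their union covers the image: a
    partition of the pixels.
    """
    labels = np.unique(label_img)
    return [BinaryMask(label_img == lab) for lab in labels]


def select_hole_cluster(masks: list[BinaryMask], gray: RasterImage) -> BinaryMask:
    """Pick the cluster whose pixels are darkest on the original grayscale.

    Holes in SEM surface micrographs image darker than the surrounding
    film, so the hole cluster is the one with the lowest mean intensity.
    Ties (e.g. a synthetic image of identical tones) resolve to the
    smaller mask, with a warning.
    """
    if not masks:
        raise ValueError("empty mask list")
    if gray.channels != 1:
        raise ValueError("select_hole_cluster expects a single-channel image")
    g = np.asarray(gray.pixels, dtype=np.float64)
    stats = []
    for i, m in enumerate(masks):
        cnt = m.foreground_count
        mean = g[m.values].mean() if cnt else np.inf
        stats.append((mean, cnt, i))
    means = [s[0] for s in stats if np.isfinite(s[0])]
    if len(means) > 1 and max(means) - min(means) < 1e-12:
        logger.warning("all clusters have equal mean intensity; picking the smallest mask")
    stats.sort(key=lambda s: (s[0], s[1], s[2]))
    return masks[stats[0][2]]
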