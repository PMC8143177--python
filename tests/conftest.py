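import numpy as np
import pytest

from porefilm import FilmSpec, RasterImage


@pytest.fixture
def two_tone():
    """20x20 image with exactly two intensity values (40 dark, 220 bright)."""
    px = np.where(np.arange(400).reshape(20, 20) % 7 < 3, 40, 220).astype(float)
    return RasterImage(px)


@pytest.fixture
def noiseless_film_spec():
    """Factory for the reference recovery condition: 10 circular r=5 pores."""

    def make(seed: int = 0, **overrides) -> FilmSpec:
        kw = dict(
            width=200,
            height=200,
            n_holes=10,
            radius_range=(5.0, 5.0),
            ellipticity_range=(1.0, 1.0),
            texture_amplitude=10.0,
            gaussian_sigma=0.0,
            impulse_fraction=0.0,
            seed=seed,
        )
        kw.update(overrides)
        return FilmSpec(**kw)

    return make


def brute_force_kmeans_wcss(X: np.ndarray, k: int) -> float:
    """Exhaustive-assignment optimum of the K-means objective (tiny n only)."""
    import itertools

    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        a = np.asarray(assign)
        wcss = 0.0
        for j in range(k):
            pts = X[a == j]
            if len(pts):
                wcss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, wcss)
    return best


def brute_force_otsu(values: np.ndarray) -> int:
    """Literal scan of all 255 candidate thresholds maximizing between-class variance."""
    v = np.asarray(values, dtype=np.float64).reshape(-1)
    best_t, best_var = 0, -1.0
    for t in range(255):
        c0, c1 = v[v <= t], v[v > t]
        if len(c0) == 0 or len(c1) == 0:
            var = 0.0
        else:
            w0, w1 = len(c0) / len(v), len(c1) / len(v)
            var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_t, best_var = t, var
    return best_t
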