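"""2-D/3-D layout of structure components and embedding quality metrics.

The layout stage builds a fuzzy neighbor graph over the selected multiscale
diffusion components and optimizes a low-dimensional embedding by
attractive/repulsive cross-entropy descent (UMAP), with ``min_dist`` (M)
as the effective minimum distance between embedded points and ``spread``
(S) as their effective scale. Initialization uses the first ``d`` selected
components (spectral-style), which together with a fixed seed makes runs
reproducible.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.manifold import trustworthiness as _sk_trustworthiness

from .diffusion import DiffusionSpace
from .io import ValidationError


@dataclass
class LayoutEmbedding:
    """Low-dimensional layout coordinates plus the parameters that made them."""

    coords: np.ndarray  # (n, d), mean-centered
    min_dist: float
    spread: float
    seed: int
    source: str  # fingerprint of the input component matrix

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _fingerprint(components: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(components).tobytes()).hexdigest()[:16]


def embed_layout(
    space: DiffusionSpace | np.ndarray,
    min_dist: float = 0.3,
    spread: float = 1.0,
    d: int = 2,
    seed: int = 0,
    n_neighbors: int | None = None,
) -> LayoutEmbedding:
    """Optimize a ``d``-dimensional layout of the structure components.

    Deterministic for a fixed seed; coordinates are centered at the origin.
    """
    import umap  # deferred: numba compilation is slow to import

    if isinstance(space, DiffusionSpace):
        components = space.structure_components
        if space.selected_m < 2:
            raise ValidationError("need at least 2 selected components")
        if n_neighbors is None:
            n_neighbors = space.params.n_neighbors
    else:
        components = np.asarray(space, dtype=float)
        if components.shape[1] < 2:
            raise ValidationError("need at least 2 components")
        if n_neighbors is None:
            n_neighbors = 15
    if min_dist <= 0:
        raise ValidationError("min_dist (M) must be > 0")
    if spread < min_dist:
        raise ValidationError("spread (S) must be >= min_dist (M)")
    if d not in (2, 3):
        raise ValidationError("layout dimension must be 2 or 3")

    n = components.shape[0]
    n_neighbors = max(2, min(n_neighbors, n - 1))
    init = components[:, :d].copy()
    # scale the spectral-style init to the ~10-unit box umap expects
    span = np.abs(init).max()
    if span > 0:
        init *= 10.0 / span
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=d,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            spread=spread,
            init=init,
            random_state=seed,
            metric="euclidean",
        )
        coords = reducer.fit_transform(components)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return LayoutEmbedding(
        coords=coords,
        min_dist=min_dist,
        spread=spread,
        seed=seed,
        source=_fingerprint(components),
    )


def trustworthiness(high: np.ndarray, low: np.ndarray, k: int = 15) -> float:
    """Rank-based trustworthiness of the low-dimensional embedding in [0, 1].

    Penalizes k-neighbors in the embedding that are not k-neighbors in the
    original space, with the standard rank normalization.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    n = high.shape[0]
    if low.shape[0] != n:
        raise ValidationError("high and low spaces must have the same n")
    if not 1 <= k < n / 2:
        raise ValidationError("k must satisfy 1 <= k < n/2")
    return float(_sk_trustworthiness(high, low, n_neighbors=k))


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two angle vectors.

    Based on pairwise angle differences, so it is invariant to rotation of
    either variable and robust when the angles cover the whole circle;
    reflection flips the sign. Used to score recovery of a cyclic manifold
    coordinate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    return float((sa * sb).sum() / denom)


class StructureLayout(BaseEstimator):
    """Estimator wrapper around :func:`embed_layout`.

    Attributes after fit: ``embedding_`` (centered coordinates),
    ``layout_`` (:class:`LayoutEmbedding`).
    """

    def __init__(
        self,
        min_dist: float = 0.3,
        spread: float = 1.0,
        n_dims: int = 2,
        seed: int = 0,
        n_neighbors: int | None = None,
    ):
        self.min_dist = min_dist
        self.spread = spread
        self.n_dims = n_dims
        self.seed = seed
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None) -> "StructureLayout":
        self.layout_ = embed_layout(
            X,
            min_dist=self.min_dist,
            spread=self.spread,
            d=self.n_dims,
            seed=self.seed,
            n_neighbors=self.n_neighbors,
        )
        self.embedding_ = self.layout_.coords
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_
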