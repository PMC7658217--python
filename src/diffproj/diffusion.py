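"""Adaptive anisotropic diffusion maps with multiscale eigengap selection.

The embedding is built in five stages: exact k-nearest-neighbor search,
density-adaptive Gaussian affinities (per-cell bandwidth at a chosen
neighbor rank), anisotropic normalization of the kernel (alpha = 1
approximates the Laplace-Beltrami operator, decoupling manifold geometry
from sampling density), eigendecomposition of the row-stochastic diffusion
operator via its symmetric conjugate, and multiscale weighting of the
nontrivial eigenvectors by lambda/(1 - lambda) — the closed-form sum of
each component's contribution over random walks of every length. The
number of "structure components" carrying signal is chosen by the largest
eigengap in the nontrivial spectrum (floor of 2), with manual override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

from .config import DbmapParams
from .io import ValidationError

_EXACT_KNN_LIMIT = 8192


class NeighborGraph(NamedTuple):
    """kNN result: per-row neighbor ids and ascending distances."""

    indices: np.ndarray  # (n, K) int
    distances: np.ndarray  # (n, K) float, row-sorted ascending
    metric: str


@dataclass
class DiffusionOperator:
    """Row-stochastic Markov operator on the cell graph.

    ``P`` is the operator itself; ``degrees`` holds the row sums of the
    anisotropic kernel, from which the symmetric conjugate
    ``D^{1/2} P D^{-1/2}`` is formed for real eigendecomposition.
    """

    P: sp.csr_matrix
    degrees: np.ndarray
    alpha: float
    symmetric_conjugate: bool = True


@dataclass
class DiffusionSpace:
    """Eigenvalues plus multiscaled nontrivial diffusion components.

    ``components`` has one column per nontrivial eigenvector, scaled by
    lambda/(1-lambda); ``selected_m`` is the eigengap-chosen number of
    structure components.
    """

    eigenvalues: np.ndarray  # descending, length N, eigenvalues[0] ~ 1
    components: np.ndarray  # (n, N-1) multiscaled
    selected_m: int
    params: DbmapParams = field(default_factory=DbmapParams)
    gap_flagged: bool = False

    @property
    def structure_components(self) -> np.ndarray:
        return self.components[:, : self.selected_m]


def build_knn(X: np.ndarray, K: int, metric: str = "euclidean") -> NeighborGraph:
    """Exact K nearest neighbors (self excluded), ties broken by index.

    An exact chunked brute-force search with deterministic index
    tie-breaking is used up to 8192 points; above that the tree/brute
    backend of scikit-learn is used.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("input contains non-finite values")
    n = X.shape[0]
    if K >= n:
        raise ValidationError(f"K={K} must be < number of points {n}")
    if n <= _EXACT_KNN_LIMIT:
        indices = np.empty((n, K), dtype=int)
        distances = np.empty((n, K))
        chunk = max(1, int(2**24 // max(n, 1)))
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            D = pairwise_distances(X[start:stop], X, metric=metric)
            rows = np.arange(start, stop)
            D[np.arange(stop - start), rows] = np.inf  # exclude self
            # stable lexicographic order: distance first, index second
            col_idx = np.broadcast_to(np.arange(n), D.shape)
            order = np.lexsort((col_idx, D), axis=1)[:, :K]
            indices[start:stop] = order
            distances[start:stop] = np.take_along_axis(D, order, axis=1)
    else:
        nn = NearestNeighbors(n_neighbors=K + 1, metric=metric).fit(X)
        dist, idx = nn.kneighbors(X)
        indices = np.empty((n, K), dtype=int)
        distances = np.empty((n, K))
        for i in range(n):
            mask = idx[i] != i
            if mask.sum() == K + 1:  # self not returned (duplicate points)
                mask[-1] = False
            indices[i] = idx[i][mask][:K]
            distances[i] = dist[i][mask][:K]
    return NeighborGraph(indices=indices, distances=distances, metric=metric)


def adaptive_affinity(graph: NeighborGraph, bandwidth_rank: int) -> sp.csr_matrix:
    """Density-adaptive Gaussian affinity, symmetrized by averaging.

    Each cell's bandwidth sigma_i is its distance to the
    ``bandwidth_rank``-th neighbor (falling back to the smallest positive
    row distance, then to 1 for fully duplicated rows); affinities are
    ``exp(-d_ij^2 / sigma_i^2)`` on graph edges and ``W = (w + w^T)/2``
    with zero diagonal.
    """
    n, K = graph.indices.shape
    if not 1 <= bandwidth_rank <= K:
        raise ValidationError("bandwidth_rank must lie in [1, K]")
    sigma = graph.distances[:, bandwidth_rank - 1].copy()
    for i in np.flatnonzero(sigma == 0):
        positive = graph.distances[i][graph.distances[i] > 0]
        sigma[i] = positive[0] if positive.size else 1.0
    w = np.exp(-(graph.distances**2) / sigma[:, None] ** 2)
    rows = np.repeat(np.arange(n), K)
    W = sp.csr_matrix((w.ravel(), (rows, graph.indices.ravel())), shape=(n, n))
    W = (W + W.T) / 2.0
    W.setdiag(0.0)
    W.eliminate_zeros()
    return W.tocsr()


def anisotropic_markov(W: sp.spmatrix, alpha: float = 1.0) -> DiffusionOperator:
    """Anisotropic normalization then row normalization of the kernel.

    ``W_ij`` is divided by ``(q_i q_j)^alpha`` with ``q`` the kernel
    degrees; the result is row-normalized into a stochastic operator.
    """
    W = sp.csr_matrix(W)
    if (W != W.T).nnz:
        raise ValidationError("affinity must be symmetric")
    q = np.asarray(W.sum(axis=1)).ravel()
    if np.any(q == 0):
        bad = np.flatnonzero(q == 0)
        raise ValidationError(f"isolated cells with zero affinity: {bad.tolist()[:10]}")
    if alpha > 0:
        inv_q = sp.diags(q ** (-alpha))
        W_tilde = inv_q @ W @ inv_q
    else:
        W_tilde = W
    d = np.asarray(W_tilde.sum(axis=1)).ravel()
    P = sp.diags(1.0 / d) @ W_tilde
    return DiffusionOperator(P=P.tocsr(), degrees=d, alpha=alpha)


def eigendecompose(op: DiffusionOperator, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-N eigenpairs of P, descending, real via the symmetric conjugate.

    Eigenvectors are unit-norm with the sign fixed so the largest-magnitude
    entry is positive.
    """
    n = op.P.shape[0]
    if N >= n:
        raise ValidationError(f"N={N} must be < number of cells {n}")
    d_half = np.sqrt(op.degrees)
    S = sp.diags(d_half) @ op.P @ sp.diags(1.0 / d_half)
    S = (S + S.T) / 2.0  # symmetrize away round-off
    if n <= max(3 * N, 200):
        vals, vecs = np.linalg.eigh(np.asarray(S.todense()))
        vals, vecs = vals[-N:], vecs[:, -N:]
    else:
        try:
            # fixed start vector: bit-deterministic regardless of global RNG
            v0 = np.full(n, 1.0 / np.sqrt(n))
            vals, vecs = spla.eigsh(S, k=N, which="LA", v0=v0)
        except spla.ArpackNoConvergence as err:  # pragma: no cover
            raise ArithmeticError(
                f"eigendecomposition failed to converge: {err}"
            ) from err
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # conjugate back to eigenvectors of P
    vecs = vecs / d_half[:, None]
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(N)])
    flip[flip == 0] = 1.0
    return vals, vecs * flip


def multiscale_select(
    eigenvalues: np.ndarray,
    eigenvectors: np.ndarray,
    params: DbmapParams | None = None,
    n_select: int | None = None,
) -> DiffusionSpace:
    """Multiscale the nontrivial spectrum and pick components by eigengap.

    The trivial first pair (lambda ~ 1, constant eigenvector) is dropped;
    each remaining eigenvector is scaled by lambda/(1-lambda), capping
    lambda at 1 - 1e-9. ``selected_m`` is the position of the largest
    consecutive eigenvalue gap in the nontrivial spectrum, floored at 2;
    ``n_select`` overrides it.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.size < 3:
        raise ValidationError("need at least 3 eigenpairs")
    if abs(eigenvalues[0] - 1.0) > 1e-6:
        warnings.warn(f"leading eigenvalue {eigenvalues[0]:.6f} differs from 1")
    lam = eigenvalues[1:].copy()
    lam_capped = np.minimum(lam, 1 - 1e-9)
    scale = lam_capped / (1.0 - lam_capped)
    components = eigenvectors[:, 1:] * scale[None, :]

    gaps = lam[:-1] - lam[1:]
    flagged = False
    if gaps.size == 0:
        selected = 2
        flagged = True
    elif gaps.max() - gaps.min() < 1e-8:  # flat spectrum: no eigengap exists
        selected = 2
        flagged = True
    else:
        selected = int(np.argmax(gaps)) + 1
        if selected < 2:
            selected = 2
            flagged = True
    selected = min(selected, components.shape[1])
    if n_select is not None:
        if not 1 <= n_select <= components.shape[1]:
            raise ValidationError("n_select out of range")
        selected = n_select
        flagged = False
    return DiffusionSpace(
        eigenvalues=eigenvalues,
        components=components,
        selected_m=selected,
        params=params if params is not None else DbmapParams(),
        gap_flagged=flagged,
    )


class DiffusionMap(BaseEstimator):
    """Adaptive anisotropic diffusion-map embedding (fit/fit_transform).

    Parameters
    ----------
    n_components : int
        Number N of eigenpairs to compute; N-1 nontrivial components result.
    n_neighbors : int
        K nearest neighbors per cell for the adaptive kernel.
    metric : {"euclidean", "cosine"}
    alpha : float
        Anisotropy exponent in [0, 1]; 1 approximates Laplace-Beltrami.
    bandwidth_rank : int or None
        Neighbor rank fixing each cell's kernel bandwidth (None -> ceil(K/2)).
    n_select : int or None
        Manual override of the eigengap component count.

    Attributes
    ----------
    eigenvalues_ : (N,) descending eigenvalues of the diffusion operator.
    embedding_ : (n, N-1) multiscaled nontrivial components.
    selected_m_ : eigengap-chosen number of structure components.
    operator_ : DiffusionOperator
    space_ : DiffusionSpace
    """

    def __init__(
        self,
        n_components: int = 30,
        n_neighbors: int = 15,
        metric: str = "euclidean",
        alpha: float = 1.0,
        bandwidth_rank: int | None = None,
        n_select: int | None = None,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.alpha = alpha
        self.bandwidth_rank = bandwidth_rank
        self.n_select = n_select

    def _params(self) -> DbmapParams:
        return DbmapParams(
            n_components=self.n_components,
            n_neighbors=self.n_neighbors,
            metric=self.metric,
            alpha=self.alpha,
            bandwidth_rank=self.bandwidth_rank,
        )

    def fit(self, X, y=None) -> "DiffusionMap":
        X = np.asarray(X, dtype=float)
        params = self._params()
        params.validate(n_cells=X.shape[0])
        graph = build_knn(X, params.n_neighbors, params.metric)
        W = adaptive_affinity(graph, params.effective_bandwidth_rank())
        op = anisotropic_markov(W, params.alpha)
        vals, vecs = eigendecompose(op, params.n_components)
        space = multiscale_select(vals, vecs, params=params, n_select=self.n_select)
        self.neighbor_graph_ = graph
        self.operator_ = op
        self.space_ = space
        self.eigenvalues_ = space.eigenvalues
        self.embedding_ = space.components
        self.selected_m_ = space.selected_m
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the selected structure components."""
        return self.fit(X).space_.structure_components


def fit_dbmap(X: np.ndarray, params: DbmapParams | None = None) -> DiffusionSpace:
    """Compose the full diffusion pipeline; deterministic given X and params."""
    params = params or DbmapParams()
    est = DiffusionMap(
        n_components=params.n_components,
        n_neighbors=params.n_neighbors,
        metric=params.metric,
        alpha=params.alpha,
        bandwidth_rank=params.bandwidth_rank,
    )
    est.fit(X)
    space = est.space_
    space.params = params
    return space
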