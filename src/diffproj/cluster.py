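"""Shared-nearest-neighbor modularity clustering on structure components.

A kNN graph is built on the structure components; edge weights are the
Jaccard overlap of the two cells' neighbor sets (each set includes the
cell itself), edges below the prune threshold are dropped, and communities
are found by modularity optimization (Louvain by default, Leiden as an
alternative backend). Singleton communities are relabeled REMOVED and the
remaining clusters are renumbered by decreasing size.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .diffusion import build_knn
from .io import ValidationError

#: Label assigned to cells in singleton/undersized communities.
REMOVED = -1


@dataclass
class ClusterPartition:
    """Per-cell labels (``REMOVED`` = -1 for dropped singletons) and metadata."""

    labels: np.ndarray
    resolution: float
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.sizes:
            kept = self.labels[self.labels != REMOVED]
            uniq, counts = np.unique(kept, return_counts=True)
            self.sizes = dict(zip(uniq.tolist(), counts.tolist()))

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def cluster_ids(self) -> list[int]:
        return sorted(self.sizes)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def snn_graph(
    components: np.ndarray,
    k: int = 20,
    prune: float = 1.0 / 15.0,
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Neighbor sets include the cell itself (size k+1); edges with Jaccard
    weight below ``prune`` are removed. Returns a symmetric sparse matrix
    with zero diagonal.
    """
    components = np.asarray(components, dtype=float)
    n = components.shape[0]
    if components.ndim != 2 or components.shape[1] < 2:
        raise ValidationError("components must be an n x m matrix with m >= 2")
    k = min(k, n - 1)
    graph = build_knn(components, k)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate(
        [np.column_stack([np.arange(n), graph.indices]).ravel()]
    )
    B = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, cols)), shape=(n, n)
    )
    inter = (B @ B.T).tocoo()
    set_size = k + 1
    union = 2 * set_size - inter.data
    jaccard = inter.data / union
    W = sp.csr_matrix((jaccard, (inter.row, inter.col)), shape=(n, n))
    W.setdiag(0.0)
    W.data[W.data < prune] = 0.0
    W.eliminate_zeros()
    return W


def cluster_snn(
    graph: sp.spmatrix,
    resolution: float = 0.8,
    seed: int = 0,
    backend: str = "louvain",
) -> ClusterPartition:
    """Modularity clustering of an SNN graph; deterministic given seed.

    ``backend`` is ``louvain`` (igraph multilevel) or ``leiden``
    (leidenalg RBConfiguration). Communities of size < 2 are relabeled
    ``REMOVED``; remaining clusters are renumbered by decreasing size.
    """
    W = sp.csr_matrix(graph)
    n = W.shape[0]
    if n == 0:
        raise ValidationError("graph is empty")
    coo = sp.triu(W, k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    weights = coo.data.tolist()

    if backend == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        membership = np.array(
            g.community_multilevel(
                weights=weights if weights else None, resolution=resolution
            ).membership
        )
    elif backend == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights if weights else None,
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = np.array(part.membership)
    else:
        raise ValueError(f"unknown backend '{backend}'")

    labels = np.full(n, REMOVED, dtype=int)
    uniq, counts = np.unique(membership, return_counts=True)
    kept = uniq[counts >= 2]
    # renumber by decreasing size, ties by original community id
    order = sorted(kept, key=lambda c: (-counts[uniq == c][0], c))
    for new_id, community in enumerate(order):
        labels[membership == community] = new_id
    return ClusterPartition(labels=labels, resolution=resolution)


class SNNGraphClustering(ClusterMixin, BaseEstimator):
    """SNN-Jaccard graph + modularity clustering as a sklearn estimator.

    Attributes after fit: ``labels_`` (-1 marks removed singletons),
    ``partition_``, ``graph_``.
    """

    def __init__(
        self,
        k: int = 20,
        prune: float = 1.0 / 15.0,
        resolution: float = 0.8,
        seed: int = 0,
        backend: str = "louvain",
    ):
        self.k = k
        self.prune = prune
        self.resolution = resolution
        self.seed = seed
        self.backend = backend

    def fit(self, X, y=None) -> "SNNGraphClustering":
        self.graph_ = snn_graph(np.asarray(X, dtype=float), k=self.k, prune=self.prune)
        self.partition_ = cluster_snn(
            self.graph_,
            resolution=self.resolution,
            seed=self.seed,
            backend=self.backend,
        )
        self.labels_ = self.partition_.labels
        return self
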