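"""Synthetic single-cell data with ground truth.

Generators cover the structures the analysis stages assume: well-separated
Gaussian mixtures (clustering geometry), noisy circles (cyclic manifolds),
negative-binomial count matrices with planted cluster markers (marker
detection), branching negative-binomial lineages with known pseudotime
(trajectory inference), and injected doublets. Counts follow a
gamma-Poisson (negative binomial) model with log-normal per-cell library
factors — the accepted generative caricature of droplet UMI data. Every
generator is bit-reproducible per seed and emits truth aligned with its
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a synthetic CountMatrix.

    ``labels`` holds cluster ids or branch ids (0 = pre-branch root for
    lineages); ``pseudotime_true`` is None for non-trajectory data;
    ``planted_markers`` maps gene symbol -> cluster/branch id.
    """

    labels: np.ndarray
    pseudotime_true: np.ndarray | None = None
    doublet_flag: np.ndarray | None = None
    planted_markers: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def frame(self, barcodes: np.ndarray) -> pd.DataFrame:
        data = {"label": self.labels}
        if self.pseudotime_true is not None:
            data["pseudotime_true"] = self.pseudotime_true
        if self.doublet_flag is not None:
            data["doublet_flag"] = self.doublet_flag.astype(int)
        return pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"))


def _barcodes(n: int, prefix: str = "cell") -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}_{i:0{width}d}" for i in range(n)], dtype=object)


def _features(n: int) -> pd.DataFrame:
    width = max(4, len(str(n)))
    ids = [f"ENSG{i:0{width}d}" for i in range(n)]
    symbols = [f"GENE{i:0{width}d}" for i in range(n)]
    return pd.DataFrame({"id": ids, "symbol": symbols})


def make_gaussian_mixture(
    n_per: int,
    k: int,
    dim: int,
    sep: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """``k`` isotropic unit-variance Gaussians with equidistant centers.

    Centers sit at mutual distance ``sep * sqrt(dim)``; for ``k <= dim``
    this is exact (scaled coordinate axes), otherwise centers are random
    directions with approximately that spacing.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if sep < 0:
        raise ValidationError("sep must be >= 0")
    rng = np.random.default_rng(seed)
    target = sep * np.sqrt(dim)
    if k == 1:
        centers = np.zeros((1, dim))
    elif k <= dim:
        centers = np.eye(k, dim) * target / np.sqrt(2.0)
    else:
        directions = rng.normal(size=(k, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        centers = directions * target / np.sqrt(2.0)
    labels = np.repeat(np.arange(k), n_per)
    X = rng.normal(size=(k * n_per, dim)) + centers[labels]
    return X, labels


def make_noisy_circle(
    n: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Points on the unit circle plus isotropic Gaussian noise.

    Returns the 2-D coordinates and the true angle of each point
    (uniform on [0, 2*pi)).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    X = np.column_stack([np.cos(theta), np.sin(theta)])
    X += rng.normal(scale=noise_sd, size=X.shape) if noise_sd > 0 else 0.0
    return X, theta


def _sample_counts(
    mu: np.ndarray,
    nb_dispersion: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma-Poisson counts with shape ``nb_dispersion`` (None -> Poisson)."""
    if nb_dispersion is None or np.isinf(nb_dispersion):
        return rng.poisson(mu)
    lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
    return rng.poisson(lam)


def simulate_cluster_counts(
    n_cells: int = 2000,
    n_genes: int = 1000,
    n_clusters: int = 5,
    markers_per_cluster: int = 3,
    fold: float = 4.0,
    de_prob: float = 0.1,
    background_fold: float = 2.5,
    nb_dispersion: float | None = 10.0,
    lib_size_sd: float = 0.3,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial count mixture with planted fold-change markers.

    Each cluster carries a broad expression program — ``de_prob`` of all
    genes up-regulated by ``background_fold`` (the canonical 10% DE
    fraction of droplet-data simulators) — plus ``markers_per_cluster``
    strong canonical markers up-regulated by ``fold`` from a well-expressed
    baseline. Only the canonical markers are recorded in
    ``planted_markers``. Cells get log-normal library factors
    (sd ``lib_size_sd``); counts are gamma-Poisson with shape
    ``nb_dispersion``.
    """
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=-0.5, sigma=1.2, size=n_genes)
    labels = rng.integers(0, n_clusters, size=n_cells)
    n_de = int(round(de_prob * n_genes))
    n_special = n_clusters * (markers_per_cluster + n_de)
    if n_special > n_genes:
        raise ValidationError("n_genes too small for the requested DE structure")
    special = rng.choice(n_genes, size=n_special, replace=False)
    marker_genes = special[: n_clusters * markers_per_cluster].reshape(
        n_clusters, markers_per_cluster
    )
    de_genes = special[n_clusters * markers_per_cluster :].reshape(n_clusters, n_de)
    # canonical markers start from a solidly expressed baseline
    base[marker_genes.ravel()] = rng.lognormal(
        mean=0.5, sigma=0.3, size=marker_genes.size
    )
    lib = np.exp(rng.normal(0.0, lib_size_sd, size=n_cells))

    log_mu = np.tile(np.log(base), (n_cells, 1))
    for c in range(n_clusters):
        members = labels == c
        log_mu[np.ix_(members, de_genes[c])] += np.log(background_fold)
        log_mu[np.ix_(members, marker_genes[c])] += np.log(fold)
    mu = np.exp(log_mu) * lib[:, None]
    counts = _sample_counts(mu, nb_dispersion, rng)

    features = _features(n_genes)
    symbols = features["symbol"].to_numpy()
    planted = {
        str(symbols[g]): int(c)
        for c in range(n_clusters)
        for g in marker_genes[c]
    }
    matrix = CountMatrix(
        values=sp.csr_matrix(counts),
        barcodes=_barcodes(n_cells),
        features=features,
    )
    truth = SyntheticTruth(
        labels=labels,
        planted_markers=planted,
        params={
            "n_clusters": n_clusters,
            "fold": fold,
            "de_prob": de_prob,
            "background_fold": background_fold,
            "nb_dispersion": nb_dispersion,
            "lib_size_sd": lib_size_sd,
            "seed": seed,
        },
    )
    return matrix, truth


def simulate_branching_counts(
    n_cells: int = 3000,
    n_genes: int = 1500,
    n_branches: int = 3,
    depth_genes_per_branch: int = 150,
    fold: float = 4.0,
    nb_dispersion: float | None = 10.0,
    lib_size_sd: float = 0.3,
    seed: int = 0,
    branch_point: float = 0.3,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Branching negative-binomial lineage with known pseudotime.

    Each cell draws a depth ``u ~ Uniform[0, 1]`` and a latent branch.
    A root program (its own ``depth_genes_per_branch`` marker genes,
    up-regulated by ``fold`` at u = 0) decays log-linearly with depth.
    Cells commit to their branch at the branch point (u = 0.3); committed
    cells interpolate log-linearly from the root program to their leaf
    program over the full depth range, so branch markers of a cell at
    depth u are elevated by ``fold**u`` — commitment is switch-like, as in
    lineage priming. Cells before the branch point are statistically
    identical across branches. Truth labels are the branch id
    (1..n_branches) past the branch point and 0 (root) before it.
    """
    if n_branches < 1:
        raise ValidationError("n_branches must be >= 1")
    if fold < 1:
        raise ValidationError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=-0.5, sigma=1.2, size=n_genes)
    u = rng.uniform(0.0, 1.0, size=n_cells)
    branch = rng.integers(1, n_branches + 1, size=n_cells)
    lib = np.exp(rng.normal(0.0, lib_size_sd, size=n_cells))

    n_programs = n_branches + 1  # root + leaves
    if n_programs * depth_genes_per_branch > n_genes:
        raise ValidationError(
            "n_genes too small for (n_branches + 1) * depth_genes_per_branch "
            "program genes"
        )
    program_genes = rng.choice(
        n_genes, size=n_programs * depth_genes_per_branch, replace=False
    ).reshape(n_programs, depth_genes_per_branch)
    root_genes, leaf_genes = program_genes[0], program_genes[1:]

    log_mu = np.tile(np.log(base), (n_cells, 1))
    log_mu[:, root_genes] += np.log(fold) * (1.0 - u)[:, None]
    committed = u > branch_point
    for b in range(n_branches):
        members = (branch == b + 1) & committed
        log_mu[np.ix_(members, leaf_genes[b])] += np.log(fold) * u[members, None]
    mu = np.exp(log_mu) * lib[:, None]
    counts = _sample_counts(mu, nb_dispersion, rng)

    features = _features(n_genes)
    symbols = features["symbol"].to_numpy()
    planted = {str(symbols[g]): 0 for g in root_genes}
    for b in range(n_branches):
        planted.update({str(symbols[g]): b + 1 for g in leaf_genes[b]})
    labels = np.where(u > branch_point, branch, 0)
    matrix = CountMatrix(
        values=sp.csr_matrix(counts),
        barcodes=_barcodes(n_cells),
        features=features,
    )
    truth = SyntheticTruth(
        labels=labels,
        pseudotime_true=u,
        planted_markers=planted,
        params={
            "n_branches": n_branches,
            "fold": fold,
            "nb_dispersion": nb_dispersion,
            "lib_size_sd": lib_size_sd,
            "branch_point": branch_point,
            "seed": seed,
        },
    )
    return matrix, truth


def inject_doublets(
    matrix: CountMatrix,
    rate: float,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Append ``floor(rate * n)`` synthetic doublets.

    Each doublet is the entry-wise sum of two random distinct parent cells,
    halved and rounded down. Returns the augmented matrix and the boolean
    doublet flags over all cells (original order first).
    """
    if not 0 <= rate < 1:
        raise ValidationError("rate must lie in [0, 1)")
    n = matrix.n_cells
    n_doublets = int(np.floor(rate * n))
    flags = np.zeros(n + n_doublets, dtype=bool)
    if n_doublets == 0:
        return matrix, flags[:n]
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_doublets):
        a, b = rng.choice(n, size=2, replace=False)
        merged = np.asarray((matrix.values[a] + matrix.values[b]).todense()).ravel()
        rows.append(merged // 2)
    doublet_block = sp.csr_matrix(np.vstack(rows))
    values = sp.vstack([matrix.values, doublet_block]).tocsr()
    barcodes = np.concatenate(
        [matrix.barcodes, _barcodes(n_doublets, prefix="doublet")]
    )
    flags[n:] = True
    out = CountMatrix(
        values=values,
        barcodes=barcodes,
        features=matrix.features.reset_index(drop=True),
    )
    return out, flags
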