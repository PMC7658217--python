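"""QC filtering, log-normalization, variable-gene selection and scaling.

The stages mirror the standard per-sample single-cell workflow: per-cell QC
metrics with knee-point threshold suggestion on the log-rank curve,
counts-per-cell log-normalization against a fixed size factor (default
10,000), mean-binned dispersion ranking of highly variable genes, and
per-gene z-scaling with clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import QCThresholds
from .io import CountMatrix, ValidationError


@dataclass
class ExpressionMatrix:
    """Real-valued cell-by-gene expression with a layer tag.

    ``layer`` is one of ``lognorm``, ``scaled`` or ``imputed``. The lognorm
    layer is nonnegative and kept sparse; scaled/imputed layers are dense.
    """

    values: sp.csr_matrix | np.ndarray
    layer: str
    barcodes: np.ndarray
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in ("lognorm", "scaled", "imputed"):
            raise ValidationError(f"unknown layer '{self.layer}'")
        n = self.values.shape[0]
        if len(self.barcodes) != n or len(self.features) != self.values.shape[1]:
            raise ValidationError("identifier lengths do not match values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def symbols(self) -> np.ndarray:
        return self.features["symbol"].to_numpy(dtype=object)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_vector(self, symbol: str) -> np.ndarray:
        idx = np.flatnonzero(self.symbols == symbol)
        if idx.size == 0:
            raise KeyError(f"gene '{symbol}' not present")
        col = self.values[:, idx[0]]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()


class KneePoint(NamedTuple):
    """Result of knee detection: suggested threshold, its rank, warning flag."""

    threshold: float
    rank: int
    flagged: bool


def qc_metrics(matrix: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC table with columns ``nreads``, ``ngenes``, ``mito_pc``.

    ``mito_pc`` is the percentage of counts on genes whose symbol starts
    with ``mito_prefix`` (0 for empty cells).
    """
    if not mito_prefix:
        raise ValueError("mito_prefix must be nonempty")
    X = matrix.values
    nreads = np.asarray(X.sum(axis=1)).ravel()
    ngenes = np.diff(X.indptr) if sp.isspmatrix_csr(X) else np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = np.array(
        [str(s).startswith(mito_prefix) for s in matrix.symbols], dtype=bool
    )
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pc = np.where(nreads > 0, 100.0 * mito_counts / np.maximum(nreads, 1), 0.0)
    return pd.DataFrame(
        {"nreads": nreads, "ngenes": ngenes, "mito_pc": mito_pc},
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def detect_knee(values: np.ndarray) -> KneePoint:
    """Suggest a lower threshold at the knee of the log10 rank curve.

    Values are sorted descending and log10-transformed; the knee is the
    point of maximum perpendicular distance to the chord joining the first
    and last points of the (rank, log10 value) curve. A flat or log-linear
    curve has no knee; the minimum (resp. the distance argmax, which is then
    endpoint-adjacent) is returned with ``flagged=True``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("knee detection needs at least 3 cells")
    if np.any(values <= 0):
        raise ValidationError("knee detection requires positive values")
    order = np.sort(values)[::-1]
    if order[0] == order[-1]:
        return KneePoint(threshold=float(order[-1]), rank=len(order) - 1, flagged=True)
    y = np.log10(order)
    x = np.arange(len(y), dtype=float)
    # Perpendicular distance of each point to the first-last chord.
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    idx = int(np.argmax(dist))
    flagged = dist[idx] < 1e-6
    return KneePoint(threshold=float(order[idx]), rank=idx, flagged=flagged)


def apply_qc(
    matrix: CountMatrix,
    thresholds: QCThresholds,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, np.ndarray]:
    """Filter cells by the set QC bounds; genes are never removed.

    Returns the filtered matrix and the boolean keep flags (original order).
    Raises :class:`ValidationError` naming the binding constraints when no
    cell survives.
    """
    thresholds.validate()
    metrics = qc_metrics(matrix, mito_prefix)
    keep = np.ones(matrix.n_cells, dtype=bool)
    fail_counts: dict[str, int] = {}

    def bound(column: str, limit, lower: bool) -> None:
        nonlocal keep
        if limit is None:
            return
        ok = metrics[column] >= limit if lower else metrics[column] <= limit
        ok = ok.to_numpy()
        name = f"{'min' if lower else 'max'}_{column}"
        fail_counts[name] = int((~ok).sum())
        keep &= ok

    bound("nreads", thresholds.min_nreads, True)
    bound("nreads", thresholds.max_nreads, False)
    bound("ngenes", thresholds.min_ngenes, True)
    bound("ngenes", thresholds.max_ngenes, False)
    bound("mito_pc", thresholds.max_mito_pc, False)

    if not keep.any():
        worst = max(fail_counts, key=fail_counts.get) if fail_counts else "none"
        raise ValidationError(
            f"no cells survive QC; most binding constraint: {worst} "
            f"(per-constraint failures: {fail_counts})"
        )
    return matrix.subset_cells(keep), keep


def lognormalize(matrix: CountMatrix, size_factor: float = 10_000.0) -> ExpressionMatrix:
    """Counts-per-cell log-normalization: ``ln(1 + count * size_factor / total)``.

    Sparsity is preserved. Cells with zero total counts are rejected; run
    :func:`apply_qc` first.
    """
    if size_factor <= 0:
        raise ValueError("size_factor must be > 0")
    totals = np.asarray(matrix.values.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        bad = matrix.barcodes[totals == 0][:5]
        raise ValidationError(f"zero-count cells present (e.g. {list(bad)})")
    X = matrix.values.tocsr().astype(float)
    row_scale = size_factor / totals
    X = sp.diags(row_scale) @ X
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        values=X.tocsr(),
        layer="lognorm",
        barcodes=matrix.barcodes.copy(),
        features=matrix.features.reset_index(drop=True),
    )


def _gene_moments(X: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene population mean and variance of expm1(lognorm) values."""
    E = X.copy()
    E.data = np.expm1(E.data)
    mean = np.asarray(E.mean(axis=0)).ravel()
    sq = E.copy()
    sq.data = sq.data**2
    mean_sq = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    return mean, var


def select_hvg(
    matrix: ExpressionMatrix,
    n_hvg: int = 5_000,
    n_mean_bins: int = 20,
) -> np.ndarray:
    """Rank genes by mean-binned standardized dispersion; return top ``n_hvg``.

    Dispersion is variance/mean on the expm1 scale. Genes are placed into
    ``n_mean_bins`` equal-frequency mean bins; dispersion is z-standardized
    within each bin. Zero-variance genes never outrank positive-dispersion
    genes; remaining ties break by gene index. If ``n_hvg`` exceeds the
    number of eligible (nonzero-mean) genes, all eligible genes are
    returned with a warning.
    """
    if matrix.layer != "lognorm":
        raise ValidationError("select_hvg expects the lognorm layer")
    X = sp.csr_matrix(matrix.values)
    mean, var = _gene_moments(X)
    eligible = mean > 0
    if eligible.sum() < n_mean_bins:
        raise ValidationError(
            f"need >= {n_mean_bins} genes with nonzero mean, have {int(eligible.sum())}"
        )
    idx = np.flatnonzero(eligible)
    disp = var[idx] / mean[idx]

    # Equal-frequency bins over the mean, deterministic order by (mean, index).
    order = np.lexsort((idx, mean[idx]))
    bins = np.empty(idx.size, dtype=int)
    bins[order] = np.floor(
        np.arange(idx.size) * n_mean_bins / idx.size
    ).astype(int)

    z = np.zeros(idx.size)
    for b in range(n_mean_bins):
        members = bins == b
        if not members.any():
            continue
        d = disp[members]
        sd = d.std()
        z[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    positive = var[idx] > 0
    # Sort: positive-dispersion genes first, then z descending, then index.
    rank_key = np.lexsort((idx, -z, ~positive))
    ranked = idx[rank_key]
    if n_hvg > ranked.size:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds {ranked.size} eligible genes; returning all"
        )
        return ranked
    return ranked[:n_hvg]


def scale_genes(
    matrix: ExpressionMatrix,
    genes: np.ndarray,
    clip: float = 10.0,
) -> ExpressionMatrix:
    """Z-score the selected genes (population SD) and clip to ``[-clip, clip]``.

    Zero-variance genes map to all-zero columns.
    """
    genes = np.asarray(genes, dtype=int)
    if genes.size == 0:
        raise ValidationError("gene list must be nonempty")
    if clip <= 0:
        raise ValueError("clip must be > 0")
    X = matrix.values[:, genes]
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    out = np.zeros_like(X, dtype=float)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mean[nz]) / sd[nz]
    np.clip(out, -clip, clip, out=out)
    return ExpressionMatrix(
        values=out,
        layer="scaled",
        barcodes=matrix.barcodes.copy(),
        features=matrix.features.iloc[genes].reset_index(drop=True),
    )


def preprocess_counts(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    size_factor: float = 10_000.0,
    n_hvg: int = 5_000,
    n_mean_bins: int = 20,
    scale_clip: float = 10.0,
    mito_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, ExpressionMatrix, np.ndarray]:
    """Full preprocessing: QC -> lognorm -> HVG -> scaled HVG matrix.

    Returns ``(scaled, lognorm, hvg_indices)`` where ``scaled`` covers only
    the selected genes.
    """
    if thresholds is not None:
        matrix, _ = apply_qc(matrix, thresholds, mito_prefix)
    else:
        totals = np.asarray(matrix.values.sum(axis=1)).ravel()
        if np.any(totals == 0):
            matrix = matrix.subset_cells(totals > 0)
    lognorm = lognormalize(matrix, size_factor)
    hvg = select_hvg(lognorm, n_hvg=n_hvg, n_mean_bins=n_mean_bins)
    scaled = scale_genes(lognorm, hvg, clip=scale_clip)
    return scaled, lognorm, hvg
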