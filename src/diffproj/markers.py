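"""Marker detection, dot-plot statistics, cell-cycle scoring, doublet flags.

Markers are found one-vs-rest per cluster with a two-sided Wilcoxon
rank-sum test (exact for small groups, normal approximation with tie
correction otherwise), ranked by natural-log fold change computed with a
+1 pseudocount on the expm1 scale, and Benjamini-Hochberg adjusted within
each cluster.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import REMOVED, ClusterPartition
from .io import ValidationError
from .preprocess import ExpressionMatrix

_EXACT_MAX_GROUP = 25
_ENUM_LIMIT = 200_000


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups have <= 25 observations and the null
    distribution is tractable (scipy's exact method without ties; midrank
    enumeration when ties are present and C(n1+n2, n1) <= 2e5); otherwise
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 <= _EXACT_MAX_GROUP and n2 <= _EXACT_MAX_GROUP:
        if not has_ties:
            return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
        if math.comb(n1 + n2, n1) <= _ENUM_LIMIT:
            return _exact_enumeration_p(x, y)
    return float(stats.mannwhitneyu(x, y, method="asymptotic").pvalue)


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all rank assignments (midranks)."""
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    observed = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        total += 1
        if abs(ranks[list(subset)].sum() - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values, dtype=float)


def rank_markers(
    expr: ExpressionMatrix,
    partition: ClusterPartition,
    min_pct: float = 0.1,
    min_logfc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker table sorted by log fold change within cluster.

    Columns: gene, cluster, log_fc, p_value, p_adjusted, pct_in, pct_out.
    A gene is tested for a cluster when it is expressed (value > 0) in at
    least ``min_pct`` of in-cluster or out-of-cluster cells and
    ``|log_fc| >= min_logfc`` where ``log_fc = ln(mean(expm1 in)+1) -
    ln(mean(expm1 out)+1)``. Clusters of size < 3 are skipped with a
    warning; REMOVED cells never enter any test.
    """
    if expr.layer != "lognorm":
        raise ValidationError("rank_markers expects the lognorm layer")
    labels = partition.labels
    clusters = [c for c in partition.cluster_ids()]
    retained = [c for c in clusters if partition.sizes[c] >= 3]
    if len([c for c in clusters if c != REMOVED]) < 2:
        raise ValidationError("need at least 2 retained clusters")
    skipped = sorted(set(clusters) - set(retained))
    if skipped:
        warnings.warn(f"skipping clusters of size < 3: {skipped}")

    X = sp.csr_matrix(expr.values)
    E = X.copy()
    E.data = np.expm1(E.data)
    valid = labels != REMOVED
    symbols = expr.symbols
    rows = []
    for c in retained:
        in_mask = labels == c
        out_mask = valid & ~in_mask
        n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
        if n_out == 0:
            continue
        mean_in = np.asarray(E[in_mask].mean(axis=0)).ravel()
        mean_out = np.asarray(E[out_mask].mean(axis=0)).ravel()
        pct_in = np.asarray((X[in_mask] > 0).sum(axis=0)).ravel() / n_in
        pct_out = np.asarray((X[out_mask] > 0).sum(axis=0)).ravel() / n_out
        log_fc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        candidates = np.flatnonzero(
            ((pct_in >= min_pct) | (pct_out >= min_pct))
            & (np.abs(log_fc) >= min_logfc)
        )
        if candidates.size == 0:
            continue
        Xin = _as_dense(X[in_mask][:, candidates])
        Xout = _as_dense(X[out_mask][:, candidates])
        if n_in > _EXACT_MAX_GROUP and n_out > _EXACT_MAX_GROUP:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.mannwhitneyu(Xin, Xout, axis=0, method="asymptotic")
            pvals = np.nan_to_num(np.atleast_1d(res.pvalue), nan=1.0)
        else:
            pvals = np.array(
                [
                    wilcoxon_rank_sum(Xin[:, j], Xout[:, j])
                    for j in range(candidates.size)
                ]
            )
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, g in enumerate(candidates):
            rows.append(
                {
                    "gene": symbols[g],
                    "cluster": c,
                    "log_fc": log_fc[g],
                    "p_value": pvals[j],
                    "p_adjusted": padj[j],
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "log_fc", "p_value", "p_adjusted", "pct_in", "pct_out"],
    )
    if len(table):
        table = table.sort_values(
            ["cluster", "log_fc"], ascending=[True, False]
        ).reset_index(drop=True)
    return table


def top_markers(table: pd.DataFrame, n: int = 2) -> pd.DataFrame:
    """The ``n`` genes with the highest log fold change per cluster."""
    return (
        table.sort_values(["cluster", "log_fc"], ascending=[True, False])
        .groupby("cluster", sort=True)
        .head(n)
        .reset_index(drop=True)
    )


def dotplot_stats(
    expr: ExpressionMatrix,
    partition: ClusterPartition,
    genes: list[str],
    expr_threshold: float = 0.0,
) -> pd.DataFrame:
    """Numeric content of a dot plot: per (cluster, gene) statistics.

    Columns: cluster, gene, fraction_expressing (share of cluster cells
    with value > ``expr_threshold``), mean_expression. Genes missing from
    the matrix are reported in the ``missing_genes`` DataFrame attribute,
    not fatal.
    """
    symbols = expr.symbols
    present = [g for g in genes if g in set(symbols)]
    missing = [g for g in genes if g not in set(symbols)]
    if missing:
        warnings.warn(f"genes not in matrix: {missing}")
    X = sp.csr_matrix(expr.values)
    col_of = {s: i for i, s in enumerate(symbols)}
    rows = []
    for c in partition.cluster_ids():
        members = partition.members(c)
        sub = X[members]
        for g in present:
            col = np.asarray(sub[:, col_of[g]].todense()).ravel()
            rows.append(
                {
                    "cluster": c,
                    "gene": g,
                    "fraction_expressing": float((col > expr_threshold).mean())
                    if len(col)
                    else 0.0,
                    "mean_expression": float(col.mean()) if len(col) else 0.0,
                }
            )
    out = pd.DataFrame(rows, columns=["cluster", "gene", "fraction_expressing", "mean_expression"])
    out.attrs["missing_genes"] = missing
    return out


def score_gene_set(
    expr: ExpressionMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Module score: mean set expression minus mean bin-matched control.

    Genes are placed into ``n_bins`` equal-frequency bins by average
    expression; for each set gene, ``n_ctrl`` control genes are drawn
    (seeded) from its bin and the control mean is taken over the pooled
    draw.
    """
    symbols = expr.symbols
    col_of = {s: i for i, s in enumerate(symbols)}
    set_idx = [col_of[g] for g in gene_set if g in col_of]
    missing = [g for g in gene_set if g not in col_of]
    if not set_idx:
        raise ValidationError(f"no gene-set genes in matrix; missing: {missing}")
    X = sp.csr_matrix(expr.values)
    n_genes = X.shape[1]
    gene_mean = np.asarray(X.mean(axis=0)).ravel()
    order = np.lexsort((np.arange(n_genes), gene_mean))
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.floor(np.arange(n_genes) * n_bins / n_genes).astype(int)

    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in set_idx:
        pool = np.flatnonzero(bins == bins[g])
        replace = pool.size < n_ctrl
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=replace).tolist())
    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def score_cell_cycle(
    expr: ExpressionMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M module scores and phase call.

    Phase is G1 when both scores are <= 0, otherwise the argmax score.
    Returns a DataFrame with columns s_score, g2m_score, phase.
    """
    s_score = score_gene_set(expr, s_genes, n_bins, n_ctrl, seed)
    g2m_score = score_gene_set(expr, g2m_genes, n_bins, n_ctrl, seed + 1)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=pd.Index(expr.barcodes, name="barcode"),
    )


def flag_doublet_clusters(
    markers: pd.DataFrame,
    partition: ClusterPartition,
    min_top_logfc: float = 0.5,
) -> pd.DataFrame:
    """Advisory doublet flags: clusters without a distinctive top marker.

    A cluster is flagged when its best marker's log fold change is below
    ``min_top_logfc`` (clusters with no marker surviving the filters score
    0). Removal is left to the caller.
    """
    best = markers.groupby("cluster")["log_fc"].max() if len(markers) else pd.Series(dtype=float)
    rows = []
    for c in partition.cluster_ids():
        top = float(best.get(c, 0.0))
        rows.append({"cluster": c, "top_log_fc": top, "doublet_flag": top < min_top_logfc})
    return pd.DataFrame(rows, columns=["cluster", "top_log_fc", "doublet_flag"])
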