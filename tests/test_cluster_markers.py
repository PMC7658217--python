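import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import diffproj as dp
from diffproj.cluster import REMOVED
from diffproj.io import ValidationError


def _expr(values, symbols=None, layer="lognorm"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    symbols = symbols or [f"G{j}" for j in range(g)]
    return dp.ExpressionMatrix(
        values=sp.csr_matrix(values) if layer == "lognorm" else values,
        layer=layer,
        barcodes=np.array([f"c{i}" for i in range(n)], dtype=object),
        features=pd.DataFrame({"id": symbols, "symbol": symbols}),
    )


class TestSnnGraph:
    def test_jaccard_weights_match_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        k = 6
        W = dp.snn_graph(X, k=k, prune=0.0)
        g = dp.build_knn(X, k)
        sets = [set(g.indices[i]) | {i} for i in range(50)]
        for i, j in zip(*W.nonzero()):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            assert W[i, j] == pytest.approx(inter / union)

    def test_duplicate_points_share_full_neighborhood(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        W = dp.snn_graph(X, k=4, prune=0.0)
        # within a duplicated block every cell has the identical neighbor set
        assert W[0, 1] == pytest.approx(1.0)

    def test_prune_removes_weak_edges(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        dense = dp.snn_graph(X, k=5, prune=0.0)
        pruned = dp.snn_graph(X, k=5, prune=1 / 15)
        assert pruned.nnz <= dense.nnz
        assert (pruned.data >= 1 / 15).all()


class TestClusterSnn:
    def _two_cliques_graph(self):
        block = np.ones((100, 100)) - np.eye(100)
        return sp.csr_matrix(sp.block_diag([block, block]))

    def test_two_disconnected_cliques(self):
        graph = self._two_cliques_graph()
        part = dp.cluster_snn(graph, resolution=0.8, seed=0)
        assert part.n_clusters == 2
        assert sorted(part.sizes.values()) == [100, 100]

    def test_louvain_agrees_with_leiden_oracle(self):
        graph = self._two_cliques_graph()
        louvain = dp.cluster_snn(graph, resolution=0.8, seed=0, backend="louvain")
        leiden = dp.cluster_snn(graph, resolution=0.8, seed=0, backend="leiden")
        np.testing.assert_array_equal(louvain.labels, leiden.labels)

    def test_isolated_vertex_removed(self):
        block = np.ones((50, 50)) - np.eye(50)
        graph = sp.csr_matrix(sp.block_diag([block, np.zeros((1, 1))]))
        part = dp.cluster_snn(graph, seed=0)
        assert part.labels[-1] == REMOVED

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(size=(80, 3)), rng.normal(size=(80, 3)) + 5])
        graph = dp.snn_graph(X, k=10)
        a = dp.cluster_snn(graph, seed=42)
        b = dp.cluster_snn(graph, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_renumbered_by_size(self):
        big = np.ones((60, 60)) - np.eye(60)
        small = np.ones((20, 20)) - np.eye(20)
        graph = sp.csr_matrix(sp.block_diag([small, big]))
        part = dp.cluster_snn(graph, seed=0)
        assert part.sizes[0] == 60  # largest community is cluster 0
        assert part.sizes[1] == 20


def _enumeration_oracle(x, y):
    """Independent exact two-sided rank-sum p by subset enumeration."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    mu = n1 * (len(combined) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(combined)), n1):
        total += 1
        hits += abs(ranks[list(comb)].sum() - mu) >= obs - 1e-12
    return hits / total


class TestWilcoxon:
    def test_spec_example_exact(self):
        assert dp.wilcoxon_rank_sum([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)

    def test_exact_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 6, size=n2).astype(float)
            assert dp.wilcoxon_rank_sum(x, y) == pytest.approx(
                _enumeration_oracle(x, y)
            )

    def test_approximation_close_to_exact_at_moderate_sizes(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=22)
            y = rng.normal(loc=0.5, size=24)
            exact = float(stats.mannwhitneyu(x, y, method="exact").pvalue)
            approx = float(stats.mannwhitneyu(x, y, method="asymptotic").pvalue)
            assert abs(exact - approx) < 0.01
            # tie-free sizes <= 25 take the exact path
            assert dp.wilcoxon_rank_sum(x, y) == pytest.approx(exact)


class TestRankMarkers:
    def _partitioned_expr(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(1.0, size=(60, 20)).astype(float)
        base[:30, 0] += 4.0  # strong marker of cluster 0
        labels = np.array([0] * 30 + [1] * 30)
        return _expr(np.log1p(base)), dp.ClusterPartition(labels=labels, resolution=0.8)

    def test_marker_table_schema_and_ordering(self):
        expr, part = self._partitioned_expr()
        table = dp.rank_markers(expr, part)
        assert list(table.columns) == [
            "gene", "cluster", "log_fc", "p_value", "p_adjusted", "pct_in", "pct_out",
        ]
        for _, sub in table.groupby("cluster"):
            assert (sub["log_fc"].diff().dropna() <= 1e-12).all()
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_planted_marker_found(self):
        expr, part = self._partitioned_expr()
        table = dp.rank_markers(expr, part)
        top = dp.top_markers(table, n=2)
        assert "G0" in set(top[top.cluster == 0].gene)

    def test_identical_distributions_excluded_by_logfc_filter(self):
        rng = np.random.default_rng(6)
        values = np.log1p(rng.poisson(2.0, size=(40, 5)).astype(float))
        part = dp.ClusterPartition(labels=np.array([0] * 20 + [1] * 20), resolution=0.8)
        table = dp.rank_markers(_expr(values), part, min_logfc=0.25)
        # no gene differs 1.28-fold between identically distributed halves
        assert len(table) == 0

    def test_needs_two_clusters(self):
        values = np.log1p(np.ones((10, 3)))
        part = dp.ClusterPartition(labels=np.zeros(10, dtype=int), resolution=0.8)
        with pytest.raises(ValidationError):
            dp.rank_markers(_expr(values), part)

    def test_bh_adjustment_monotone_in_p(self):
        expr, part = self._partitioned_expr()
        table = dp.rank_markers(expr, part, min_logfc=0.0, min_pct=0.0)
        for _, sub in table.groupby("cluster"):
            s = sub.sort_values("p_value")
            assert (s["p_adjusted"].diff().dropna() >= -1e-12).all()


class TestDotplotStats:
    def test_fraction_and_mean(self):
        values = np.zeros((10, 2))
        values[:3, 0] = 2.0
        part = dp.ClusterPartition(labels=np.zeros(10, dtype=int), resolution=0.8)
        out = dp.dotplot_stats(_expr(values), part, ["G0", "G1"])
        row = out[(out.cluster == 0) & (out.gene == "G0")].iloc[0]
        assert row.fraction_expressing == pytest.approx(0.3)
        assert row.mean_expression == pytest.approx(0.6)
        absent = out[(out.cluster == 0) & (out.gene == "G1")].iloc[0]
        assert absent.fraction_expressing == 0.0
        assert absent.mean_expression == 0.0

    def test_missing_gene_reported_not_fatal(self):
        values = np.ones((4, 1))
        part = dp.ClusterPartition(labels=np.zeros(4, dtype=int), resolution=0.8)
        with pytest.warns(UserWarning, match="NOPE"):
            out = dp.dotplot_stats(_expr(values), part, ["G0", "NOPE"])
        assert out.attrs["missing_genes"] == ["NOPE"]
        assert set(out.gene) == {"G0"}

    def test_single_cell_cluster_fraction_binary(self):
        values = np.array([[1.0], [0.0]])
        part = dp.ClusterPartition(
            labels=np.array([0, 1]), resolution=0.8, sizes={0: 1, 1: 1}
        )
        out = dp.dotplot_stats(_expr(values), part, ["G0"])
        assert set(out.fraction_expressing) <= {0.0, 1.0}


class TestCellCycle:
    def test_all_zero_matrix_is_all_g1(self):
        values = np.zeros((20, 60))
        scores = dp.score_cell_cycle(
            _expr(values), ["G0", "G1"], ["G2", "G3"], seed=0
        )
        assert (scores.phase == "G1").all()
        assert (scores.s_score == 0).all()

    def test_phase_rules(self):
        # cells expressing the S set score positive for S and get called S
        rng = np.random.default_rng(7)
        values = np.log1p(rng.poisson(1.0, size=(60, 150)).astype(float))
        values[:30, :10] += 2.0  # S program in first half
        s_genes = [f"G{j}" for j in range(10)]
        g2m_genes = [f"G{j}" for j in range(10, 20)]
        scores = dp.score_cell_cycle(_expr(values), s_genes, g2m_genes, seed=1)
        assert (scores.phase[:30] == "S").mean() > 0.9
        called_g1 = scores[(scores.s_score <= 0) & (scores.g2m_score <= 0)]
        assert (called_g1.phase == "G1").all()

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            dp.score_cell_cycle(_expr(np.ones((5, 4))), ["NOPE"], ["G0"])

    def test_agrees_with_scanpy_scoring(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata

        rng = np.random.default_rng(8)
        values = np.log1p(rng.poisson(2.0, size=(100, 120)).astype(float))
        values[:40, :8] += 1.5
        gene_set = [f"G{j}" for j in range(8)]
        ours = dp.score_gene_set(_expr(values), gene_set, seed=0)
        adata = anndata.AnnData(values)
        adata.var_names = [f"G{j}" for j in range(120)]
        scanpy.tl.score_genes(adata, gene_set, ctrl_size=100, n_bins=24, random_state=0)
        theirs = adata.obs["score"].to_numpy()
        # the control draws differ (per-gene bin-matched vs pooled), so the
        # scores agree strongly but not exactly
        assert np.corrcoef(ours, theirs)[0, 1] > 0.9


class TestDoubletFlags:
    def test_vacuous_threshold_flags_nothing(self, cluster_pipeline):
        part = cluster_pipeline["clustering"].partition_
        table = dp.rank_markers(cluster_pipeline["lognorm"], part)
        flags = dp.flag_doublet_clusters(table, part, min_top_logfc=0.0)
        assert not flags.doublet_flag.any()

    def test_doublet_cluster_flagged_marker_cluster_not(self):
        rng = np.random.default_rng(9)
        n_genes = 40
        a = rng.poisson(1.0, size=(40, n_genes)).astype(float)
        b = rng.poisson(1.0, size=(40, n_genes)).astype(float)
        a[:, 0] += 6.0  # cluster A marker
        b[:, 1] += 6.0  # cluster B marker
        doublets = (a[:20] + b[:20]) / 2.0  # averaged parent profiles
        values = np.log1p(np.vstack([a, b, doublets]))
        labels = np.array([0] * 40 + [1] * 40 + [2] * 20)
        part = dp.ClusterPartition(labels=labels, resolution=0.8)
        table = dp.rank_markers(_expr(values), part)
        flags = dp.flag_doublet_clusters(table, part, min_top_logfc=0.5)
        flagged = set(flags[flags.doublet_flag].cluster)
        assert 2 in flagged
        assert 0 not in flagged and 1 not in flagged


class TestLibrarySizeStability:
    def test_detected_genes_stable_across_clusters(self, cluster_sim):
        matrix, truth = cluster_sim
        ngenes = np.diff(matrix.values.indptr)
        means = [
            ngenes[truth.labels == c].mean() for c in np.unique(truth.labels)
        ]
        assert (max(means) - min(means)) / np.mean(means) < 0.10
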