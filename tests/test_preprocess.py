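import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import diffproj as dp
from diffproj.io import ValidationError


def _count_matrix(values: np.ndarray, symbols=None) -> dp.CountMatrix:
    n, g = values.shape
    symbols = symbols or [f"G{j}" for j in range(g)]
    return dp.CountMatrix(
        values=sp.csr_matrix(values),
        barcodes=np.array([f"c{i}" for i in range(n)], dtype=object),
        features=pd.DataFrame({"id": symbols, "symbol": symbols}),
    )


class TestQCMetrics:
    def test_arithmetic(self, tiny_counts):
        m = dp.qc_metrics(tiny_counts, mito_prefix="MT-")
        # cell 0: counts [2,3,0], gene 0 mitochondrial
        assert m.loc["bc0", "nreads"] == 5
        assert m.loc["bc0", "ngenes"] == 2
        assert m.loc["bc0", "mito_pc"] == pytest.approx(40.0)

    def test_empty_cell_has_zero_mito(self, tiny_counts):
        m = dp.qc_metrics(tiny_counts)
        assert m.loc["bc1", "nreads"] == 0
        assert m.loc["bc1", "mito_pc"] == 0.0

    def test_all_mito_is_100(self):
        cm = _count_matrix(np.array([[3, 4]]), symbols=["MT-A", "MT-B"])
        assert dp.qc_metrics(cm).loc["c0", "mito_pc"] == pytest.approx(100.0)


def _knee_oracle(values: np.ndarray) -> int:
    """Exhaustive chord-distance maximizer on the (rank, log10) curve."""
    y = np.log10(np.sort(values)[::-1])
    x = np.arange(len(y), dtype=float)
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    best, best_d = 0, -1.0
    for i in range(len(y)):
        p = np.array([x[i], y[i]]) - p0
        d = abs(chord[0] * p[1] - chord[1] * p[0]) / np.linalg.norm(chord)
        if d > best_d:
            best, best_d = i, d
    return best


class TestDetectKnee:
    def test_hand_example(self):
        knee = dp.detect_knee(np.array([1000, 950, 900, 870, 100, 90, 80.0]))
        assert knee.threshold == 870.0
        assert not knee.flagged

    def test_two_level_step(self):
        knee = dp.detect_knee(np.array([1000.0] * 5 + [10.0] * 5))
        assert knee.threshold == 1000.0

    def test_geometric_sequence_flags_no_knee(self):
        knee = dp.detect_knee(1000.0 * 0.8 ** np.arange(12))
        assert knee.flagged
        assert knee.rank in (1, 10)  # endpoint-adjacent

    def test_all_equal_returns_min_with_flag(self):
        knee = dp.detect_knee(np.full(5, 42.0))
        assert knee.threshold == 42.0
        assert knee.flagged

    def test_matches_exhaustive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            values = rng.lognormal(mean=3, sigma=1.5, size=rng.integers(5, 200))
            knee = dp.detect_knee(values)
            assert knee.rank == _knee_oracle(values)

    def test_requires_three_positive_cells(self):
        with pytest.raises(ValidationError):
            dp.detect_knee(np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            dp.detect_knee(np.array([1.0, 0.0, 2.0]))


class TestApplyQC:
    def test_min_reads_bound(self):
        cm = _count_matrix(np.diag([100, 5000, 300, 800]))
        filtered, keep = dp.apply_qc(cm, dp.QCThresholds(min_nreads=500))
        assert keep.tolist() == [False, True, False, True]
        assert filtered.n_cells == 2
        assert filtered.n_genes == cm.n_genes  # genes never removed

    def test_no_thresholds_is_identity(self, tiny_counts):
        filtered, keep = dp.apply_qc(tiny_counts, dp.QCThresholds())
        assert keep.all()
        assert (filtered.values != tiny_counts.values).nnz == 0

    def test_mito_bound(self):
        cm = _count_matrix(
            np.array([[5, 95], [15, 85]]), symbols=["MT-A", "B"]
        )
        _, keep = dp.apply_qc(cm, dp.QCThresholds(max_mito_pc=10))
        assert keep.tolist() == [True, False]

    def test_zero_survivors_names_constraint(self):
        cm = _count_matrix(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValidationError, match="min_nreads"):
            dp.apply_qc(cm, dp.QCThresholds(min_nreads=100))

    def test_keep_count_monotone_in_lower_bound(self):
        rng = np.random.default_rng(1)
        cm = _count_matrix(rng.integers(0, 20, size=(40, 10)))
        kept = []
        for lo in (1, 20, 50, 80):
            try:
                _, keep = dp.apply_qc(cm, dp.QCThresholds(min_nreads=lo))
                kept.append(keep.sum())
            except ValidationError:
                kept.append(0)
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestLognormalize:
    def test_formula(self):
        cm = _count_matrix(np.array([[1, 1, 2]]))
        em = dp.lognormalize(cm, size_factor=10_000)
        np.testing.assert_allclose(
            em.dense().ravel(), np.log([2501, 2501, 5001]), rtol=1e-12
        )

    def test_zero_count_stays_zero_and_sparsity_preserved(self):
        cm = _count_matrix(np.array([[0, 5], [3, 0]]))
        em = dp.lognormalize(cm)
        assert em.values.nnz == 2

    def test_zero_total_cell_rejected(self):
        cm = _count_matrix(np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValidationError, match="zero-count"):
            dp.lognormalize(cm)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_inverse_recovers_counts(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(8, 12))
        counts[:, 0] += 1  # no zero-total cells
        cm = _count_matrix(counts)
        em = dp.lognormalize(cm, size_factor=10_000)
        totals = counts.sum(axis=1, keepdims=True)
        recovered = np.expm1(em.dense()) * totals / 10_000
        np.testing.assert_allclose(recovered, counts, atol=1e-9)


class TestSelectHVG:
    def test_bimodal_gene_ranked_first(self):
        counts = np.ones((20, 10), dtype=int)
        counts[10:, 3] = 11  # the only gene with real variance
        cm = _count_matrix(counts)
        em = dp.lognormalize(cm)
        ranked = dp.select_hvg(em, n_hvg=5, n_mean_bins=2)
        assert ranked[0] == 3

    def test_identical_columns_tie_break_by_index(self):
        counts = np.tile(np.array([[1], [2], [4]]), (1, 6))
        em = dp.lognormalize(_count_matrix(counts))
        ranked = dp.select_hvg(em, n_hvg=6, n_mean_bins=2)
        assert ranked.tolist() == [0, 1, 2, 3, 4, 5]

    def test_planted_high_dispersion_genes_all_selected(self):
        rng = np.random.default_rng(7)
        n, g = 300, 200
        counts = rng.poisson(2.0, size=(n, g))
        hot = rng.choice(g, size=20, replace=False)
        # mean-matched but bursty: half the cells silent, half at double rate
        on = rng.random(size=(n, 20)) < 0.5
        counts[:, hot] = rng.poisson(4.0, size=(n, 20)) * on
        counts[:, 0] += 1
        em = dp.lognormalize(_count_matrix(counts))
        # without binning the dispersions are perfectly separated
        ranked = dp.select_hvg(em, n_hvg=20, n_mean_bins=1)
        assert set(hot) == set(ranked)
        # mean-binned standardization keeps them near the top
        binned = dp.select_hvg(em, n_hvg=40, n_mean_bins=10)
        assert set(hot) <= set(binned)

    def test_n_hvg_above_gene_count_warns_and_returns_all(self):
        em = dp.lognormalize(_count_matrix(np.arange(1, 13).reshape(3, 4)))
        with pytest.warns(UserWarning, match="eligible"):
            ranked = dp.select_hvg(em, n_hvg=10, n_mean_bins=2)
        assert len(ranked) == 4


class TestScaleGenes:
    def test_closed_form_z_scores(self):
        em = dp.ExpressionMatrix(
            values=np.array([[1.0], [2.0], [3.0]]),
            layer="lognorm",
            barcodes=np.array(["a", "b", "c"], dtype=object),
            features=pd.DataFrame({"id": ["g"], "symbol": ["g"]}),
        )
        scaled = dp.scale_genes(em, np.array([0]), clip=10)
        np.testing.assert_allclose(
            scaled.values.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_gene_maps_to_zero(self):
        em = dp.ExpressionMatrix(
            values=np.full((4, 1), 3.0),
            layer="lognorm",
            barcodes=np.array(list("abcd"), dtype=object),
            features=pd.DataFrame({"id": ["g"], "symbol": ["g"]}),
        )
        scaled = dp.scale_genes(em, np.array([0]))
        assert (scaled.values == 0).all()

    def test_clipping_caps_outliers_without_sign_change(self):
        x = np.zeros((101, 1))
        x[0] = 1000.0
        em = dp.ExpressionMatrix(
            values=x,
            layer="lognorm",
            barcodes=np.array([f"c{i}" for i in range(101)], dtype=object),
            features=pd.DataFrame({"id": ["g"], "symbol": ["g"]}),
        )
        scaled = dp.scale_genes(em, np.array([0]), clip=10)
        assert scaled.values.max() == 10.0
        assert (np.sign(scaled.values) == np.sign(x - x.mean())).all()

    def test_mean_zero_before_clipping(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(50, 8)) + 1
        em = dp.lognormalize(_count_matrix(counts))
        scaled = dp.scale_genes(em, np.arange(8), clip=1e9)
        assert np.abs(scaled.values.mean(axis=0)).max() < 1e-8
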