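"""QC metrics, MAD filtering, normalization, HVG, regression, PCA."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from embrisk import preprocess
from embrisk.io import CountMatrix
from embrisk.preprocess import (
    CellQCMetrics,
    ExpressionMatrix,
    compute_qc,
    mad_filter,
    normalize_log,
    regress_out,
    run_pca,
    scale_genes,
    select_hvg,
)


def _cm(values, mito=None):
    values = np.asarray(values)
    g = values.shape[1]
    return CountMatrix(
        values=sp.csr_matrix(values),
        barcodes=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"i{j}" for j in range(g)],
        gene_names=[f"g{j}" for j in range(g)],
        mito_mask=mito if mito is not None else np.zeros(g, bool),
    )


def _expr(values, **kw):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_names=[f"g{j}" for j in range(values.shape[1])],
        barcodes=[f"c{i}" for i in range(values.shape[0])],
        **kw,
    )


class TestComputeQC:
    def test_hand_computed_metrics(self):
        cm = _cm([[2, 0, 3]], mito=np.array([True, False, False]))
        m = compute_qc(cm)
        assert m.total_umi[0] == 5
        assert m.n_genes_detected[0] == 2
        assert m.mito_pct[0] == pytest.approx(40.0)

    def test_zero_total_cell_warns_and_gets_zero_mito(self):
        cm = _cm([[0, 0], [1, 2]], mito=np.array([True, False]))
        with pytest.warns(UserWarning, match="zero total"):
            m = compute_qc(cm)
        assert m.mito_pct[0] == 0.0

    def test_no_mito_genes_gives_zero_percent(self):
        m = compute_qc(_cm([[1, 2], [3, 4]]))
        assert np.all(m.mito_pct == 0)

    def test_umi_at_least_detected(self):
        cm = _cm(np.random.default_rng(0).poisson(1, (20, 10)))
        m = compute_qc(cm)
        assert np.all(m.total_umi >= m.n_genes_detected)


class TestMADFilter:
    def test_hand_computed_low_genes_cutoff(self):
        # median 99.5, unscaled MAD 1.5, low cutoff 95 -> last cell removed
        n_genes = np.array([100, 102, 98, 101, 99, 5])
        m = CellQCMetrics(total_umi=n_genes * 10.0,
                          n_genes_detected=n_genes,
                          mito_pct=np.zeros(6))
        with pytest.warns(UserWarning, match="MAD of mito_pct"):
            keep = mad_filter(m, k=3)
        assert keep.tolist() == [True] * 5 + [False]

    def test_identical_cells_all_kept_via_mad_zero_fallback(self):
        m = CellQCMetrics(np.full(5, 100.0), np.full(5, 50.0), np.full(5, 5.0))
        with pytest.warns(UserWarning, match="MAD"):
            keep = mad_filter(m)
        assert keep.all()

    def test_high_mito_is_one_sided(self):
        mito = np.array([5.0, 5.5, 4.5, 5.0, 0.0, 30.0])
        m = CellQCMetrics(np.full(6, 100.0), np.full(6, 50.0), mito)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = mad_filter(m)
        assert not keep[5]      # high-mito outlier removed
        assert keep[4]          # low mito never filtered

    def test_requires_two_cells(self):
        m = CellQCMetrics(np.array([10.0]), np.array([5.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            mad_filter(m)


class TestNormalizeLog:
    def test_hand_computed_values(self):
        # totals 10, scale 10 -> value log1p(count)
        expr = normalize_log(_cm([[1, 3, 6]]), scale=10)
        assert expr.values[0] == pytest.approx(np.log1p([1, 3, 6]))
        assert expr.normalization["scale_factor"] == 10

    def test_zero_counts_stay_zero(self):
        expr = normalize_log(_cm([[0, 5], [3, 0]]))
        assert expr.values[0, 0] == 0.0
        assert expr.values[1, 1] == 0.0

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="filter"):
            normalize_log(_cm([[0, 0], [1, 1]]))


class TestHVG:
    def test_inflated_variance_gene_selected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.05, size=(300, 10)).clip(0)
        base[:, 4] = rng.normal(1.0, 1.0, size=300).clip(0)
        mask = select_hvg(_expr(base), n=1, n_bins=2)
        assert mask[4] and mask.sum() == 1

    def test_select_all_is_identity(self):
        mask = select_hvg(_expr(np.random.default_rng(1).random((20, 6))), n=6)
        assert mask.all()

    def test_zero_mean_genes_never_beat_expressed_genes(self):
        rng = np.random.default_rng(2)
        vals = rng.random((50, 5))
        vals[:, 0] = 0.0
        mask = select_hvg(_expr(vals), n=4, n_bins=2)
        assert not mask[0]

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_hvg(_expr(np.ones((5, 3))), n=4)


class TestRegressOut:
    def test_covariate_equal_to_gene_zeroes_it(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 3))
        out = regress_out(_expr(vals), vals[:, 1])
        assert np.allclose(out.values[:, 1], 0, atol=1e-12)

    def test_zero_covariate_reduces_to_centering(self):
        vals = np.random.default_rng(1).normal(size=(25, 4))
        out = regress_out(_expr(vals), np.zeros(25))
        assert np.allclose(out.values, vals - vals.mean(0), atol=1e-12)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(0, 0.1, 40)
        out = regress_out(_expr(y[:, None]), x)
        assert abs(np.corrcoef(out.values[:, 0], x)[0, 1]) < 1e-10

    def test_collinear_covariates_named(self):
        x = np.random.default_rng(3).normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            regress_out(_expr(np.zeros((20, 2))), np.column_stack([x, 2 * x]))


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        emb, pca = run_pca(X, n_pcs=2, scale=False)
        ratio = pca.explained_variance_full_ / pca.explained_variance_full_.sum()
        assert ratio[0] == pytest.approx(1.0)

    def test_spectrum_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        _, p1 = run_pca(X, n_pcs=6, scale=False)
        _, p2 = run_pca(X @ Q, n_pcs=6, scale=False)
        assert np.allclose(p1.explained_variance_full_,
                           p2.explained_variance_full_, rtol=1e-9)
        # agreement with a direct eigendecomposition of the covariance
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(p1.explained_variance_full_, eig, rtol=1e-9)

    def test_full_rank_small_case_reconstructs_exactly(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        emb, pca = run_pca(X, n_pcs=2, scale=False)
        recon = emb @ pca.components_ + X.mean(0)
        assert np.allclose(recon, X, atol=1e-12)

    def test_variances_non_increasing_and_sum_to_total(self):
        X = np.random.default_rng(1).normal(size=(50, 8))
        _, pca = run_pca(X, n_pcs=8, scale=False)
        ev = pca.explained_variance_full_
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() == pytest.approx(pca.total_variance_, rel=1e-6)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((3, 5)), n_pcs=4)

    def test_deterministic_sign_convention(self):
        X = np.random.default_rng(2).normal(size=(30, 4))
        _, p1 = run_pca(X, n_pcs=3)
        _, p2 = run_pca(X, n_pcs=3)
        assert np.allclose(p1.components_, p2.components_)
        top = np.argmax(np.abs(p1.components_), axis=1)
        assert all(p1.components_[i, t] > 0 for i, t in enumerate(top))


def test_scale_genes_clips_and_standardizes():
    rng = np.random.default_rng(0)
    X = rng.normal(5, 2, size=(200, 3))
    X[0, 0] = 1e6
    Z = scale_genes(X, clip=10)
    assert Z.max() <= 10 and Z.min() >= -10
    assert abs(Z[:, 1].mean()) < 1e-10


def test_mad_filter_removes_planted_outliers_and_keeps_healthy(mf_prepared):
    truth, keep = mf_prepared["truth"], mf_prepared["keep"]
    assert truth.outlier_flag[keep].sum() == 0
    assert keep[~truth.outlier_flag].mean() >= 0.99


def test_mad_filter_is_idempotent_on_clean_population(mf_prepared):
    counts = mf_prepared["counts"].subset_cells(mf_prepared["keep"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        keep2 = mad_filter(compute_qc(counts))
    assert keep2.mean() >= 0.95
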