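"""Cell QC, normalization, HVG selection, covariate regression and PCA.

The QC rule is the one-sided median/MAD convention used in droplet
single-cell studies: a cell is an outlier if its mitochondrial
percentage is more than ``k`` MADs above the median, or its detected
gene count / total UMI count is more than ``k`` MADs below the median.
The MAD is unscaled by default (no 1.4826 consistency constant).

Depth normalization is ``log(1 + count * scale / cell_total)`` with a
scale factor of 10,000, recorded in the normalization provenance field.
Variable genes are picked by binned mean/dispersion ranking on the
back-transformed values.  PCA runs on z-scored, clipped values through
a deterministic sign convention (largest-magnitude loading positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .io import CountMatrix

__all__ = [
    "CellQCMetrics",
    "ExpressionMatrix",
    "compute_qc",
    "mad_filter",
    "normalize_log",
    "select_hvg",
    "regress_out",
    "scale_genes",
    "run_pca",
    "LogNormalizer",
    "HVGSelector",
    "ScaledPCA",
]


@dataclass
class CellQCMetrics:
    """Per-cell QC metrics: total UMIs, detected genes, mito percentage."""

    total_umi: np.ndarray
    n_genes_detected: np.ndarray
    mito_pct: np.ndarray
    barcodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.total_umi = np.asarray(self.total_umi, dtype=float)
        self.n_genes_detected = np.asarray(self.n_genes_detected, dtype=float)
        self.mito_pct = np.asarray(self.mito_pct, dtype=float)
        if np.any(self.mito_pct < 0) or np.any(self.mito_pct > 100):
            raise ValueError("mito_pct must lie in [0, 100]")

    @property
    def n_cells(self) -> int:
        return len(self.total_umi)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "total_umi": self.total_umi,
                "n_genes": self.n_genes_detected,
                "mito_pct": self.mito_pct,
            }
        )
        if self.barcodes is not None:
            df.insert(0, "barcode", self.barcodes)
        return df


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with provenance.

    ``values`` holds log-normalized expression (possibly residuals after
    covariate regression, in which case entries may be negative).
    """

    values: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    normalization: dict = field(default_factory=dict)
    hvg_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self.gene_names = np.asarray(list(self.gene_names), dtype=object)
        self.barcodes = np.asarray(list(self.barcodes), dtype=object)
        if len(self.gene_names) != self.values.shape[1]:
            raise ValueError("gene_names length mismatch")
        if len(self.barcodes) != self.values.shape[0]:
            raise ValueError("barcodes length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask_or_names) -> "ExpressionMatrix":
        if isinstance(mask_or_names, (list, tuple)) or (
            isinstance(mask_or_names, np.ndarray) and mask_or_names.dtype == object
        ):
            name_to_idx = {g: i for i, g in enumerate(self.gene_names)}
            missing = [g for g in mask_or_names if g not in name_to_idx]
            if missing:
                raise KeyError(f"genes not present: {missing}")
            idx = np.array([name_to_idx[g] for g in mask_or_names])
        else:
            idx = np.asarray(mask_or_names)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_names=self.gene_names[idx],
            barcodes=self.barcodes,
            normalization=dict(self.normalization),
        )


def compute_qc(counts: CountMatrix) -> CellQCMetrics:
    """Compute per-cell QC metrics from raw counts.

    Cells with zero total UMI get ``mito_pct = 0`` with a warning.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    values = counts.values
    total = np.asarray(values.sum(axis=1)).ravel().astype(float)
    n_detected = np.asarray((values > 0).sum(axis=1)).ravel().astype(float)
    if counts.mito_mask.any():
        mito = np.asarray(values[:, counts.mito_mask].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero total UMI; mito_pct set to 0",
            stacklevel=2,
        )
    mito_pct = np.zeros_like(total)
    np.divide(100.0 * mito, total, out=mito_pct, where=~zero)
    return CellQCMetrics(total, n_detected, mito_pct, barcodes=counts.barcodes)


def _median_mad(x: np.ndarray, scale: bool) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if scale:
        mad *= 1.4826
    return med, mad


def mad_filter(
    metrics: CellQCMetrics, k: float = 3.0, scale_mad: bool = False
) -> np.ndarray:
    """Boolean keep-mask from the one-sided median/MAD outlier rule.

    A cell is removed iff ``mito_pct > median + k*MAD`` or
    ``n_genes < median - k*MAD`` or ``total_umi < median - k*MAD``.
    A metric with MAD = 0 falls back to an exact-median rule on that
    metric (cells off the median on the outlying side are removed) with
    a warning; when all cells are identical nothing is removed.
    """
    if metrics.n_cells < 2:
        raise ValueError("mad_filter requires at least 2 cells")
    keep = np.ones(metrics.n_cells, dtype=bool)
    rules = (
        ("mito_pct", metrics.mito_pct, +1),
        ("n_genes", metrics.n_genes_detected, -1),
        ("total_umi", metrics.total_umi, -1),
    )
    for name, x, direction in rules:
        med, mad = _median_mad(x, scale_mad)
        if mad == 0.0:
            warnings.warn(
                f"MAD of {name} is 0; falling back to exact-median rule",
                stacklevel=2,
            )
        if direction > 0:
            keep &= x <= med + k * mad
        else:
            keep &= x >= med - k * mad
    return keep


def normalize_log(counts: CountMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalize and log1p-transform counts.

    value = log(1 + count * scale / cell_total).  Zero counts stay
    exactly zero.  Cells with zero total UMI must be filtered first.
    """
    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if np.any(total == 0):
        raise ValueError(
            "cells with zero total UMI present; run compute_qc/mad_filter first"
        )
    mat = sp.csr_matrix(counts.values, dtype=float)
    inv = scale / total
    mat = sp.diags(inv) @ mat
    mat.data = np.log1p(mat.data)
    return ExpressionMatrix(
        values=mat.toarray(),
        gene_names=counts.gene_names,
        barcodes=counts.barcodes,
        normalization={"transform": "log1p", "scale_factor": float(scale)},
    )


class HVGSelector(BaseEstimator, TransformerMixin):
    """Binned mean/dispersion highly-variable-gene selector.

    Dispersion (variance/mean) is computed on expm1 back-transformed
    values, genes are cut into ``n_bins`` equal-frequency bins by mean,
    and dispersions are z-scored within each bin.  The top ``n_top``
    genes by z-score are selected; ties resolve by ascending gene index,
    and genes with zero mean are never selected before nonzero genes.
    """

    def __init__(self, n_top: int = 2000, n_bins: int = 20):
        self.n_top = n_top
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_genes = X.shape[1]
        if self.n_top > n_genes:
            raise ValueError(f"n_top={self.n_top} exceeds {n_genes} genes")
        raw = np.expm1(X)
        mean = raw.mean(axis=0)
        var = raw.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(n_genes)
        disp = np.zeros(n_genes)
        nz = mean > 0
        disp[nz] = var[nz] / mean[nz]

        z = np.zeros(n_genes)
        if nz.any():
            bins = pd.qcut(
                mean[nz], min(self.n_bins, int(nz.sum())), duplicates="drop", labels=False
            )
            d = pd.Series(disp[nz])
            grouped = d.groupby(bins)
            mu = grouped.transform("mean").to_numpy()
            sd = grouped.transform("std").fillna(0.0).to_numpy()
            zs = np.zeros(int(nz.sum()))
            ok = sd > 0
            zs[ok] = (d.to_numpy()[ok] - mu[ok]) / sd[ok]
            z[nz] = zs
        z[~nz] = -np.inf

        order = np.lexsort((np.arange(n_genes), -z))
        mask = np.zeros(n_genes, dtype=bool)
        mask[order[: self.n_top]] = True
        self.dispersions_ = disp
        self.means_ = mean
        self.dispersions_z_ = z
        self.support_ = mask
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        return self.support_


def select_hvg(expr: ExpressionMatrix, n: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Boolean mask of the top-``n`` variable genes (see :class:`HVGSelector`)."""
    sel = HVGSelector(n_top=n, n_bins=n_bins).fit(expr.values)
    expr.hvg_mask = sel.support_
    return sel.support_


def regress_out(expr: ExpressionMatrix, covariates) -> ExpressionMatrix:
    """Replace each gene by the residual of its least-squares fit on covariates.

    ``covariates`` is (n_cells,) or (n_cells, p).  An intercept is always
    included, so an all-zero covariate reduces to per-gene mean centering.
    Rank-deficient (collinear) designs raise an error naming the columns.
    """
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == 1 and expr.n_cells != 1:
        C = C.T
    if C.shape[0] != expr.n_cells:
        raise ValueError("covariate length does not match number of cells")
    nonzero = ~np.all(C == 0, axis=0)
    C = C[:, nonzero]
    D = np.column_stack([np.ones(expr.n_cells), C])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        _, R = np.linalg.qr(D)
        dep = np.where(np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(R).max()))[0]
        cols = [("intercept" if j == 0 else f"covariate {j - 1}") for j in dep]
        raise ValueError(f"collinear covariate columns: {cols}")
    beta, *_ = np.linalg.lstsq(D, expr.values, rcond=None)
    resid = expr.values - D @ beta
    norm = dict(expr.normalization)
    norm["regressed_covariates"] = int(C.shape[1])
    return ExpressionMatrix(resid, expr.gene_names, expr.barcodes, norm)


def scale_genes(values: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Z-score each gene across cells and clip at ``+/-clip``."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return np.clip((values - mu) / sd, -clip, clip)


class ScaledPCA(BaseEstimator, TransformerMixin):
    """PCA on z-scored, clipped values with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude gene loading
    is positive; columns are ordered by decreasing explained variance.
    """

    def __init__(self, n_pcs: int = 30, clip: float = 10.0, scale: bool = True):
        self.n_pcs = n_pcs
        self.clip = clip
        self.scale = scale

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if self.n_pcs > min(n, d):
            raise ValueError(f"n_pcs={self.n_pcs} exceeds min(cells, genes)={min(n, d)}")
        if self.scale:
            X = scale_genes(X, clip=self.clip)
        pca = PCA(n_components=min(n, d), svd_solver="full")
        emb = pca.fit_transform(X)
        comps = pca.components_
        flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        flip = np.where(flip == 0, 1.0, flip)
        comps = comps * flip[:, None]
        emb = emb * flip[None, :]
        self.components_ = comps[: self.n_pcs]
        self.explained_variance_ = pca.explained_variance_[: self.n_pcs]
        self.explained_variance_full_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[: self.n_pcs]
        self.total_variance_ = float(np.var(X, axis=0, ddof=1).sum())
        return emb[:, : self.n_pcs]

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def run_pca(values: np.ndarray, n_pcs: int = 30, scale: bool = True,
            clip: float = 10.0) -> tuple[np.ndarray, ScaledPCA]:
    """PCA embedding (cells x n_pcs); see :class:`ScaledPCA`."""
    pca = ScaledPCA(n_pcs=n_pcs, clip=clip, scale=scale)
    emb = pca.fit_transform(values)
    return emb, pca


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Array-level depth normalization: log1p(x * scale / row_total)."""

    def __init__(self, scale: float = 10_000.0):
        self.scale = scale

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        total = X.sum(axis=1)
        if np.any(total == 0):
            raise ValueError("rows with zero total; filter cells first")
        return np.log1p(X * (self.scale / total)[:, None])
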