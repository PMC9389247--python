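"""Per-cell pathway activity scoring.

Converts a cells x genes expression matrix into a cells x pathways score
matrix with three independent algorithms, so that clustering can be done
in pathway space and cross-checked across scorers:

``ssgsea``
    A single-sample enrichment running sum.  Genes are ranked per cell by
    decreasing expression; in-set positions step up by a weight
    proportional to ``rank_value ** alpha`` (normalized to sum to 1 over
    set members, rank_value = G for the top gene down to 1), out-of-set
    positions step down uniformly by ``1 / (G - m)``.  The score is the
    sum over all ranked positions of (cumulative in-weight - cumulative
    out-weight).  At ``alpha = 0`` the score depends on ranks only.

``auc_recovery``
    AUCell-style area under the gene-set recovery curve within the top
    ``top_frac`` of each cell's ranking, normalized by the maximal
    achievable area for that set size, so scores lie in [0, 1].

``module_score``
    Mean expression of the set genes minus the mean of expression-matched
    control genes sampled from the same population-average-expression
    bins (the "module score" convention; 24 bins, 100 controls per gene).

All three scorers share one ranking utility whose tie policy is a seeded
random permutation of gene order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GeneSetCollection
from .preprocess import ExpressionMatrix

__all__ = [
    "EMBOLIC_PATHWAYS",
    "PathwayScoreMatrix",
    "SSGSEAScorer",
    "AUCRecoveryScorer",
    "ModuleScoreScorer",
    "score_ssgsea",
    "score_auc_recovery",
    "score_module",
    "embolic_scores",
]

#: The four coagulation / fibrin-clot pathways whose joint activation marks
#: the pro-embolic cell state.
EMBOLIC_PATHWAYS = (
    "common pathway of fibrin clot formation",
    "extrinsic pathway of fibrin clot formation",
    "formation of fibrin clot",
    "intrinsic pathway of fibrin clot formation",
)


@dataclass
class PathwayScoreMatrix:
    """Cells x pathways activity scores with a method tag."""

    scores: np.ndarray
    method: str
    pathway_names: list[str]
    params: dict = field(default_factory=dict)
    barcodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("pathway scores contain non-finite values")
        if self.scores.shape[1] != len(self.pathway_names):
            raise ValueError("pathway_names length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.pathway_names)
        if self.barcodes is not None:
            df.index = pd.Index(self.barcodes, name="barcode")
        return df


def _rank_positions(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """1-based rank position of every gene per cell (1 = highest expression).

    Ties are broken by a single seeded random permutation of gene order,
    the shared tie policy of all scorers.
    """
    n_cells, n_genes = values.shape
    perm = rng.permutation(n_genes)
    shuffled = values[:, perm]
    order = np.argsort(-shuffled, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    pos[rows, order] = np.arange(1, n_genes + 1)[None, :]
    out = np.empty_like(pos)
    out[:, perm] = pos
    return out


def _match_sets(
    sets: GeneSetCollection, gene_names: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Map set names to gene column indices; report unmatched genes."""
    name_to_idx: dict[str, int] = {}
    for i, g in enumerate(gene_names):
        name_to_idx.setdefault(str(g), i)
    matched: dict[str, np.ndarray] = {}
    unmatched: dict[str, list[str]] = {}
    for name, genes in sets.sets.items():
        idx = [name_to_idx[g] for g in genes if g in name_to_idx]
        missing = [g for g in genes if g not in name_to_idx]
        if missing:
            unmatched[name] = missing
        if idx:
            matched[name] = np.asarray(idx)
        else:
            warnings.warn(
                f"gene set {name!r} has no genes in the expression matrix; dropped",
                stacklevel=3,
            )
    if not matched:
        raise ValueError("no gene set overlaps the expression matrix")
    return matched, unmatched


class _BaseScorer(BaseEstimator, TransformerMixin):
    method = ""

    def __init__(self, sets: GeneSetCollection, gene_names, random_state: int = 0):
        self.sets = sets
        self.gene_names = np.asarray(list(gene_names), dtype=object)
        self.random_state = random_state

    def fit(self, X, y=None):
        self.matched_sets_, self.unmatched_report_ = _match_sets(
            self.sets, self.gene_names
        )
        self.pathway_names_ = list(self.matched_sets_)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class SSGSEAScorer(_BaseScorer):
    """Single-sample running-sum enrichment scorer (see module docstring)."""

    method = "ssgsea"

    def __init__(self, sets, gene_names, alpha: float = 0.25, random_state: int = 0):
        super().__init__(sets, gene_names, random_state)
        self.alpha = alpha

    def transform(self, X):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        X = np.asarray(X, dtype=float)
        n_cells, G = X.shape
        rng = np.random.default_rng(self.random_state)
        pos = _rank_positions(X, rng)  # 1 = top
        # rank value: G for the top-ranked gene, 1 for the bottom one
        rank_value = (G - pos + 1).astype(float)
        # score = sum_p (cum_in(p) - cum_out(p)); summing the step functions
        # over all G positions gives each gene a closed-form contribution of
        # weight * (G - pos + 1).
        tail = rank_value  # alias: number of positions at or after pos
        scores = np.empty((n_cells, len(self.matched_sets_)))
        for k, (name, idx) in enumerate(self.matched_sets_.items()):
            m = len(idx)
            w = rank_value[:, idx] ** self.alpha
            wsum = w.sum(axis=1)
            in_term = (w * tail[:, idx]).sum(axis=1) / wsum
            if G - m == 0:
                warnings.warn(
                    f"gene set {name!r} covers every gene; score defined as 0",
                    stacklevel=2,
                )
                scores[:, k] = 0.0
                continue
            total_tail = G * (G + 1) / 2.0
            out_term = (total_tail - tail[:, idx].sum(axis=1)) / (G - m)
            scores[:, k] = in_term - out_term
        return scores


class AUCRecoveryScorer(_BaseScorer):
    """Area under the top-``top_frac`` gene-set recovery curve, in [0, 1]."""

    method = "auc_recovery"

    def __init__(self, sets, gene_names, top_frac: float = 0.1, random_state: int = 0):
        super().__init__(sets, gene_names, random_state)
        self.top_frac = top_frac

    def transform(self, X):
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        n_cells, G = X.shape
        k = int(np.ceil(self.top_frac * G))
        rng = np.random.default_rng(self.random_state)
        pos = _rank_positions(X, rng)
        scores = np.empty((n_cells, len(self.matched_sets_)))
        for s, (name, idx) in enumerate(self.matched_sets_.items()):
            m = len(idx)
            p = pos[:, idx].astype(float)
            # a set gene at position p <= k contributes (k - p + 1) to the
            # summed cumulative-hit curve
            contrib = np.where(p <= k, k - p + 1, 0.0)
            area = contrib.sum(axis=1)
            mm = min(m, k)
            max_area = mm * k - mm * (mm - 1) / 2.0
            scores[:, s] = area / max_area
        self.top_k_ = k
        return scores


class ModuleScoreScorer(_BaseScorer):
    """Set mean minus expression-matched control mean, per cell."""

    method = "module_score"

    def __init__(self, sets, gene_names, n_bins: int = 24, n_ctrl: int = 100,
                 random_state: int = 0):
        super().__init__(sets, gene_names, random_state)
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        super().fit(X)
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        n_genes = X.shape[1]
        n_bins = min(self.n_bins, n_genes)
        bin_of = pd.qcut(
            pd.Series(mean).rank(method="first"), n_bins, labels=False, duplicates="drop"
        ).to_numpy()
        rng = np.random.default_rng(self.random_state)
        self.control_idx_ = {}
        small_bins = 0
        for name, idx in self.matched_sets_.items():
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[idx] = True
            ctrls = []
            for g in idx:
                pool = np.flatnonzero((bin_of == bin_of[g]) & ~in_set)
                if len(pool) == 0:  # bin holds only set genes
                    pool = np.flatnonzero(bin_of == bin_of[g])
                replace = len(pool) < self.n_ctrl
                small_bins += replace
                ctrls.append(rng.choice(pool, size=self.n_ctrl, replace=replace))
            self.control_idx_[name] = np.concatenate(ctrls)
        if small_bins:
            warnings.warn(
                f"{small_bins} set gene(s) sit in expression bins smaller "
                f"than n_ctrl={self.n_ctrl}; controls sampled with replacement",
                stacklevel=2,
            )
        self.bin_of_ = bin_of
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.matched_sets_)))
        for k, (name, idx) in enumerate(self.matched_sets_.items()):
            set_mean = X[:, idx].mean(axis=1)
            ctrl_mean = X[:, self.control_idx_[name]].mean(axis=1)
            scores[:, k] = set_mean - ctrl_mean
        return scores


def _run_scorer(scorer: _BaseScorer, expr: ExpressionMatrix,
                params: dict) -> PathwayScoreMatrix:
    scores = scorer.fit_transform(expr.values)
    return PathwayScoreMatrix(
        scores=scores,
        method=scorer.method,
        pathway_names=scorer.pathway_names_,
        params=params,
        barcodes=expr.barcodes,
    )


def score_ssgsea(expr: ExpressionMatrix, sets: GeneSetCollection,
                 alpha: float = 0.25, seed: int = 0) -> PathwayScoreMatrix:
    """ssGSEA-style running-sum pathway scores."""
    scorer = SSGSEAScorer(sets, expr.gene_names, alpha=alpha, random_state=seed)
    return _run_scorer(scorer, expr, {"alpha": alpha, "seed": seed})


def score_auc_recovery(expr: ExpressionMatrix, sets: GeneSetCollection,
                       top_frac: float = 0.1, seed: int = 0) -> PathwayScoreMatrix:
    """AUCell-style recovery-curve pathway scores in [0, 1]."""
    scorer = AUCRecoveryScorer(sets, expr.gene_names, top_frac=top_frac,
                               random_state=seed)
    return _run_scorer(scorer, expr, {"top_frac": top_frac, "seed": seed})


def score_module(expr: ExpressionMatrix, sets: GeneSetCollection,
                 n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> PathwayScoreMatrix:
    """Module scores: set mean minus expression-matched control mean."""
    scorer = ModuleScoreScorer(sets, expr.gene_names, n_bins=n_bins,
                               n_ctrl=n_ctrl, random_state=seed)
    return _run_scorer(scorer, expr, {"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})


def embolic_scores(expr: ExpressionMatrix, sets: GeneSetCollection,
                   seed: int = 0, n_bins: int = 24,
                   n_ctrl: int = 100) -> PathwayScoreMatrix:
    """Module scores for exactly the four fibrin-clot/coagulation pathways.

    Raises
    ------
    KeyError
        If any of the four pathway names is missing from the collection.
    """
    missing = [n for n in EMBOLIC_PATHWAYS if n not in sets.sets]
    if missing:
        raise KeyError(f"missing embolic pathway gene sets: {missing}")
    return score_module(expr, sets.subset(list(EMBOLIC_PATHWAYS)),
                        n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
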