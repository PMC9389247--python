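"""Soft-margin linear SVM trained by SMO, with recursive feature
elimination and final model selection over a penalty grid.

The classifier solves the usual soft-margin dual (penalty ``C`` bounding
the Lagrange multipliers) by sequential minimal optimization and exposes
the primal quantities: the normal vector ``w = sum_i alpha_i y_i x_i``,
the offset ``b`` averaged over free support vectors, and the decision
rule ``sign(w.x + b)`` with exact zero mapped to +1.

SVM-RFE repeats train / rank-by-``w_i^2`` / drop-the-weakest-10% for
each penalty in a grid, records stratified 10-fold CV accuracy for every
nested feature subset, and keeps the smallest subset attaining the
maximal accuracy (ties break to the smaller penalty).  Features are
z-scored before fitting since the squared-weight ranking is
scale-sensitive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._smo import offset_from_gradient, smo_solve

__all__ = [
    "ConvergenceError",
    "LabeledDataset",
    "SMOLinearSVC",
    "LinearSVMModel",
    "FeatureSelectionResult",
    "split_train_test",
    "smo_train",
    "predict",
    "cross_validate",
    "SVMRFE",
    "svm_rfe",
    "select_final_model",
]

RFE_C_GRID = (0.2, 0.6, 0.8, 1.0, 1.2, 1.6, 2.0, 2.2, 2.6, 3.0)
FINAL_C_GRID = (0.0001, 0.0005, 0.001, 0.002, 0.004, 0.008, 0.02, 0.05,
                0.2, 0.6, 1.2, 1.8, 2.4, 3.0)


class ConvergenceError(RuntimeError):
    """SMO failed to reach the KKT tolerance within the iteration budget."""

    def __init__(self, msg: str, C: float, gap: float, n_iter: int):
        super().__init__(msg)
        self.C = C
        self.gap = gap
        self.n_iter = n_iter


@dataclass
class LabeledDataset:
    """Feature matrix with +1/-1 labels and gene (feature) names."""

    x: np.ndarray
    y: np.ndarray
    gene_names: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.ascontiguousarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        self.gene_names = np.asarray(list(self.gene_names), dtype=object)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-D")
        if len(self.y) != self.x.shape[0]:
            raise ValueError("labels do not match rows of x")
        if len(self.gene_names) != self.x.shape[1]:
            raise ValueError("gene_names do not match columns of x")
        bad = set(np.unique(self.y)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    def subset_genes(self, genes: Sequence[str]) -> "LabeledDataset":
        name_to_idx = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in name_to_idx]
        if missing:
            raise KeyError(f"genes missing from dataset: {missing}")
        idx = np.array([name_to_idx[g] for g in genes])
        return LabeledDataset(self.x[:, idx], self.y, self.gene_names[idx])


def split_train_test(data: LabeledDataset, train_frac: float = 0.7,
                     seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, seeded train/test split; disjoint and exhaustive."""
    counts = pd.Series(data.y).value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("both classes need at least 2 cells to split")
    if train_frac >= 1.0:
        warnings.warn("train_frac >= 1: test set is empty", stacklevel=2)
        empty = LabeledDataset(data.x[:0], data.y[:0], data.gene_names)
        return data, empty
    idx_train, idx_test = train_test_split(
        np.arange(data.n_cells), train_size=train_frac, stratify=data.y,
        random_state=int(seed),
    )
    idx_train.sort()
    idx_test.sort()
    return (
        LabeledDataset(data.x[idx_train], data.y[idx_train], data.gene_names),
        LabeledDataset(data.x[idx_test], data.y[idx_test], data.gene_names),
    )


class SMOLinearSVC(ClassifierMixin, BaseEstimator):
    """Linear soft-margin SVM solved by sequential minimal optimization.

    Parameters
    ----------
    C : float
        Penalty bounding the dual multipliers, ``0 <= alpha_i <= C``.
    tol : float
        KKT violation tolerance declaring convergence.
    max_iter : int
        Pairwise-update budget; exceeding it with a KKT violation above
        ``tol`` raises :class:`ConvergenceError`.

    Attributes
    ----------
    coef_, intercept_ : the hyperplane (w, b)
    alpha_ : dual multipliers per training point
    support_ : indices with nonzero multipliers
    dual_objective_ : value of the minimized dual objective
    kkt_gap_ : final maximal KKT violation
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-3,
                 max_iter: int = 2_000_000, random_state: int | None = None):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, kernel: np.ndarray | None = None,
            warm_start_alpha: np.ndarray | None = None):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain exactly two classes")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        if kernel is None:
            kernel = X @ X.T
        kernel = np.ascontiguousarray(kernel, dtype=np.float64)
        if kernel.shape != (X.shape[0], X.shape[0]):
            raise ValueError("kernel must be the Gram matrix of the training rows")
        if warm_start_alpha is None:
            alpha0 = np.zeros(X.shape[0])
        else:
            alpha0 = np.clip(np.asarray(warm_start_alpha, dtype=np.float64),
                             0.0, self.C)
            # restore the equality constraint after clipping
            drift = float(alpha0 @ ypm)
            if abs(drift) > 1e-12:
                side = ypm == (1.0 if drift > 0 else -1.0)
                tot = alpha0[side].sum()
                if tot > abs(drift):
                    alpha0[side] *= 1.0 - abs(drift) / tot
                else:
                    alpha0 = np.zeros(X.shape[0])
        alpha, G, n_iter, gap = smo_solve(
            kernel, ypm, float(self.C), float(self.tol), int(self.max_iter),
            alpha0,
        )
        if gap > self.tol and n_iter >= self.max_iter:
            raise ConvergenceError(
                f"SMO did not converge at C={self.C}: KKT violation "
                f"{gap:.3e} > tol {self.tol} after {n_iter} iterations",
                C=self.C, gap=gap, n_iter=n_iter,
            )
        self.alpha_ = alpha
        self.support_ = np.flatnonzero(alpha > 1e-9)
        coef = X.T @ (alpha * ypm)
        self.coef_ = coef[None, :]
        self.intercept_ = np.array([offset_from_gradient(alpha, G, ypm, self.C)])
        self.dual_objective_ = float(0.5 * (alpha @ G - alpha.sum()))
        self.kkt_gap_ = float(gap)
        self.n_iter_ = int(n_iter)
        self._y_pm = ypm
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_[0] + self.intercept_[0]

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # exact zero maps to the positive class
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def smo_train(train: LabeledDataset, C: float, tol: float = 1e-3,
              max_iter: int = 2_000_000) -> SMOLinearSVC:
    """Fit :class:`SMOLinearSVC` on a labeled dataset."""
    return SMOLinearSVC(C=C, tol=tol, max_iter=max_iter).fit(train.x, train.y)


@dataclass
class LinearSVMModel:
    """A trained linear SVM on a named gene panel.

    The weight vector lives in standardized feature space; the stored
    per-gene mean and scale reproduce the training-time z-scoring.
    """

    gene_names: np.ndarray
    w: np.ndarray
    b: float
    C: float
    alpha: np.ndarray
    support_indices: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_names = np.asarray(list(self.gene_names), dtype=object)
        self.w = np.asarray(self.w, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale

    def align(self, X: np.ndarray, gene_names=None) -> np.ndarray:
        """Reorder columns of ``X`` to the model panel, erroring on gaps."""
        if gene_names is None:
            if X.shape[1] != len(self.gene_names):
                raise ValueError(
                    f"expected {len(self.gene_names)} panel genes, got {X.shape[1]}"
                )
            return np.asarray(X, dtype=float)
        name_to_idx = {g: i for i, g in enumerate(gene_names)}
        missing = [g for g in self.gene_names if g not in name_to_idx]
        if missing:
            raise KeyError(f"panel genes missing from input: {missing}")
        idx = np.array([name_to_idx[g] for g in self.gene_names])
        return np.asarray(X, dtype=float)[:, idx]

    def margins(self, X, gene_names=None, include_offset: bool = False) -> np.ndarray:
        Xs = self.standardize(self.align(X, gene_names))
        m = Xs @ self.w
        return m + self.b if include_offset else m

    def to_text(self) -> str:
        payload = {
            "format": "embrisk-linear-svm",
            "version": 1,
            "gene_names": list(map(str, self.gene_names)),
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
            "alpha": self.alpha.tolist(),
            "support_indices": np.asarray(self.support_indices).tolist(),
            "scaler_mean": np.asarray(self.scaler_mean).tolist(),
            "scaler_scale": np.asarray(self.scaler_scale).tolist(),
            "training_meta": self.training_meta,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "LinearSVMModel":
        payload = json.loads(text)
        if payload.get("format") != "embrisk-linear-svm":
            raise ValueError("not a serialized linear SVM model")
        return cls(
            gene_names=np.array(payload["gene_names"], dtype=object),
            w=np.array(payload["w"]),
            b=float(payload["b"]),
            C=float(payload["C"]),
            alpha=np.array(payload["alpha"]),
            support_indices=np.array(payload["support_indices"], dtype=int),
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            training_meta=payload.get("training_meta", {}),
        )


def predict(model: LinearSVMModel, X, gene_names=None) -> np.ndarray:
    """Hard-limit prediction ``sign(w.x + b)``; exact zero maps to +1."""
    m = model.margins(X, gene_names=gene_names, include_offset=True)
    return np.where(m >= 0, 1, -1)


def _fold_accuracy(K, X, y, tr, te, C, tol, max_iter, K_tr=None,
                   warm_start=None):
    """Accuracy of one fold; ``K`` is the full-data Gram matrix and
    ``K_tr`` optionally its (contiguous) training submatrix.  Returns
    ``(accuracy, alpha)`` so callers can warm-start related fits."""
    if K_tr is None:
        K_tr = np.ascontiguousarray(K[np.ix_(tr, tr)])
    clf = SMOLinearSVC(C=C, tol=tol, max_iter=max_iter)
    clf.fit(X[tr], y[tr], kernel=K_tr, warm_start_alpha=warm_start)
    ay = clf.alpha_ * clf._y_pm
    dec = K[np.ix_(te, tr)] @ ay + clf.intercept_[0]
    pred = np.where(dec >= 0, clf.classes_[1], clf.classes_[0])
    return accuracy_score(y[te], pred), clf.alpha_


def _check_cv(y: np.ndarray, k: int) -> None:
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")


def cross_validate(data: LabeledDataset, C: float, k: int = 10, seed: int = 0,
                   tol: float = 1e-3, max_iter: int = 2_000_000) -> float:
    """Mean accuracy of stratified k-fold cross-validation."""
    _check_cv(data.y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    K = data.x @ data.x.T
    accs = [
        _fold_accuracy(K, data.x, data.y, tr, te, C, tol, max_iter)[0]
        for tr, te in skf.split(data.x, data.y)
    ]
    return float(np.mean(accs))


@dataclass
class FeatureSelectionResult:
    """Outcome of SVM-RFE across the penalty grid."""

    ranked_genes: list[str]            # elimination order (weakest first)
    selected_panel: list[str]          # minimal best-accuracy subset
    cv_accuracy_path: pd.DataFrame     # size -> CV accuracy for C_used
    C_used: float
    all_paths: dict                    # C -> list of (size, accuracy)
    best_accuracy: float = float("nan")


class SVMRFE(BaseEstimator):
    """Recursive feature elimination over a penalty grid.

    Per penalty ``C``: iteratively fit, rank features by ``w_i**2``,
    drop the weakest ``step`` fraction (at least one), and record the
    stratified-CV accuracy of every nested subset.  The selected panel
    is the smallest subset attaining the maximal CV accuracy across the
    whole grid; ties break to smaller C.
    """

    def __init__(self, C_grid: Sequence[float] = RFE_C_GRID, cv: int = 10,
                 step: float = 0.1, tol: float = 1e-3,
                 max_iter: int = 2_000_000, standardize: bool = True,
                 random_state: int = 0):
        self.C_grid = C_grid
        self.cv = cv
        self.step = step
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=float)
        y = np.asarray(y)
        n, d = X.shape
        if d < 2:
            raise ValueError("RFE needs at least 2 features")
        _check_cv(y, self.cv)
        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            X = (X - mu) / sd
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=int(self.random_state))
        folds = list(skf.split(X, y))
        K_full = X @ X.T

        self.paths_ = {}
        self.elimination_order_ = {}
        subset_records = []  # (accuracy, size, C, feature-index tuple)
        for C in self.C_grid:
            K = K_full.copy()
            # per-fold contiguous Gram submatrices, downdated in lockstep
            # with K as features are eliminated
            K_folds = [np.ascontiguousarray(K[np.ix_(tr, tr)])
                       for tr, _ in folds]
            active = np.arange(d)
            order: list[int] = []
            path: list[tuple[int, float]] = []
            fold_alpha = [None] * len(folds)
            rank_alpha = None
            try:
                while active.size:
                    accs = []
                    for f, ((tr, te), K_f) in enumerate(zip(folds, K_folds)):
                        a, fold_alpha[f] = _fold_accuracy(
                            K, X[:, active], y, tr, te, C, self.tol,
                            self.max_iter, K_tr=K_f, warm_start=fold_alpha[f],
                        )
                        accs.append(a)
                    acc = float(np.mean(accs))
                    path.append((int(active.size), acc))
                    subset_records.append((acc, int(active.size), float(C),
                                           tuple(active.tolist())))
                    if active.size == 1:
                        order.append(int(active[0]))
                        break
                    clf = SMOLinearSVC(C=C, tol=self.tol, max_iter=self.max_iter)
                    clf.fit(X[:, active], y, kernel=K,
                            warm_start_alpha=rank_alpha)
                    rank_alpha = clf.alpha_
                    w2 = clf.coef_[0] ** 2
                    n_drop = max(1, int(self.step * active.size))
                    drop_local = np.argsort(w2, kind="stable")[:n_drop]
                    dropped = active[np.sort(drop_local)]
                    order.extend(int(g) for g in dropped)
                    K -= X[:, dropped] @ X[:, dropped].T
                    for (tr, _), K_f in zip(folds, K_folds):
                        Xd = X[np.ix_(tr, dropped)]
                        K_f -= Xd @ Xd.T
                    active = np.delete(active, np.sort(drop_local))
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"SVM-RFE failed at C={C}: {exc}", C=C, gap=exc.gap,
                    n_iter=exc.n_iter,
                ) from exc
            self.paths_[float(C)] = path
            self.elimination_order_[float(C)] = order

        best = max(subset_records, key=lambda r: (r[0], -r[1], -r[2]))
        self.best_accuracy_ = best[0]
        self.C_used_ = best[2]
        self.selected_idx_ = np.array(best[3], dtype=int)
        self.support_ = np.zeros(d, dtype=bool)
        self.support_[self.selected_idx_] = True
        return self


def svm_rfe(train: LabeledDataset, C_grid: Sequence[float] = RFE_C_GRID,
            cv_k: int = 10, seed: int = 0, step: float = 0.1,
            tol: float = 1e-3) -> FeatureSelectionResult:
    """Run SVM-RFE on a labeled dataset; see :class:`SVMRFE`."""
    rfe = SVMRFE(C_grid=C_grid, cv=cv_k, step=step, tol=tol,
                 random_state=seed).fit(train.x, train.y)
    names = train.gene_names
    path = pd.DataFrame(rfe.paths_[rfe.C_used_], columns=["size", "cv_accuracy"])
    return FeatureSelectionResult(
        ranked_genes=[str(names[i]) for i in rfe.elimination_order_[rfe.C_used_]],
        selected_panel=[str(names[i]) for i in rfe.selected_idx_],
        cv_accuracy_path=path,
        C_used=rfe.C_used_,
        all_paths={c: list(p) for c, p in rfe.paths_.items()},
        best_accuracy=rfe.best_accuracy_,
    )


def _metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, pos_label=1, zero_division=0),
        "recall": recall_score(y_true, y_pred, pos_label=1, zero_division=0),
        "f1": f1_score(y_true, y_pred, pos_label=1, zero_division=0),
    }


def select_final_model(
    train: LabeledDataset,
    test_sets: Sequence[LabeledDataset],
    panel: Sequence[str],
    C_grid: Sequence[float] = FINAL_C_GRID,
    tol: float = 1e-3,
    max_iter: int = 2_000_000,
    seed: int = 0,
) -> tuple[LinearSVMModel, pd.DataFrame]:
    """Train one linear SVM per penalty on the panel and pick the best.

    Reports accuracy / precision / recall / F1 per penalty per test set;
    the final model maximizes mean test accuracy (ties break to the
    smaller penalty).
    """
    if not len(panel):
        raise ValueError("panel is empty")
    if not test_sets:
        raise ValueError("at least one test set is required")
    for i, ts in enumerate(test_sets):
        if ts.n_cells == 0:
            raise ValueError(f"test set {i} is empty")
    tr = train.subset_genes(panel)
    mu = tr.x.mean(axis=0)
    sd = tr.x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xtr = (tr.x - mu) / sd

    rows = []
    fitted = {}
    for C in C_grid:
        clf = SMOLinearSVC(C=C, tol=tol, max_iter=max_iter).fit(Xtr, tr.y)
        fitted[C] = clf
        for t_i, ts in enumerate(test_sets):
            te = ts.subset_genes(panel)
            pred = clf.predict((te.x - mu) / sd)
            rows.append({"C": C, "test_set": t_i, **_metrics(te.y, pred)})
    metrics = pd.DataFrame(rows)
    mean_acc = metrics.groupby("C")["accuracy"].mean()
    best_C = float(min(mean_acc[mean_acc == mean_acc.max()].index))
    clf = fitted[best_C]
    model = LinearSVMModel(
        gene_names=np.asarray(list(panel), dtype=object),
        w=clf.coef_[0],
        b=float(clf.intercept_[0]),
        C=best_C,
        alpha=clf.alpha_,
        support_indices=clf.support_,
        scaler_mean=mu,
        scaler_scale=sd,
        training_meta={
            "seed": seed,
            "tol": tol,
            "iterations": clf.n_iter_,
            "kkt_gap": clf.kkt_gap_,
            "n_train": tr.n_cells,
        },
    )
    return model, metrics
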