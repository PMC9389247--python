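"""Per-cell embolic risk score (RS), ROC threshold calibration, and the
population-level verdict.

The risk score of a cell with panel expression ``G`` under a trained
linear SVM with weights ``w`` is

    RS = 1 + exp(-sum_i w_i G_i)

a strictly decreasing continuous function of the SVM margin.  As printed
the formula omits the hyperplane offset ``b`` (an ``include_offset``
flag adds it for sensitivity analysis) and maps positive-margin cells to
the *small* end of the scale, so which side of the RS axis is embolic is
resolved empirically by the ROC direction flag rather than assumed.
Note RS = 1 + e^-x lies in (1, inf); the commonly quoted "0 to infinity"
range is not attainable by this formula.

The operating threshold maximizes the Youden index J = sens + spec - 1
over all midpoints between consecutive sorted unique RS values; the
population verdict compares the pro-embolic proportion to an
animal-model-derived calibration constant (13.16% of a one-million-cell
dose).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .svm import LinearSVMModel

__all__ = [
    "RiskScoreVector",
    "ROCResult",
    "RiskReport",
    "compute_rs",
    "roc_threshold",
    "classify_cells",
    "population_risk",
]

CALIBRATION_FRAC = 0.1316  # pro-embolic fraction at which a 1e6-cell dose embolizes


@dataclass
class RiskScoreVector:
    """Per-cell risk scores with the margins they derive from."""

    rs: np.ndarray
    margin: np.ndarray
    orientation: str | None = None  # resolved by ROC

    def __post_init__(self) -> None:
        self.rs = np.asarray(self.rs, dtype=float)
        self.margin = np.asarray(self.margin, dtype=float)


@dataclass
class ROCResult:
    """ROC curve, AUC and the chosen Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_threshold: float
    chosen_sens: float
    chosen_spec: float
    direction: str  # high_rs_embolic | low_rs_embolic


@dataclass
class RiskReport:
    """Population-level embolic risk summary."""

    n_cells: int
    n_proembolic: int
    proportion: float
    dose_cells: float = 1e6
    calibration_frac: float = CALIBRATION_FRAC
    verdict: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        expected = self.n_proembolic / self.n_cells
        if abs(self.proportion - expected) > 1e-12:
            raise ValueError("proportion inconsistent with counts")
        self.verdict = (
            "embolic_risk" if self.proportion >= self.calibration_frac else "risk_free"
        )

    def summary(self) -> str:
        return (
            f"{self.n_proembolic}/{self.n_cells} cells pro-embolic "
            f"({100 * self.proportion:.2f}%); calibration "
            f"{100 * self.calibration_frac:.2f}% of a {self.dose_cells:.0f}-cell "
            f"dose -> verdict: {self.verdict}"
        )


def compute_rs(model: LinearSVMModel, X, gene_names=None,
               include_offset: bool = False) -> RiskScoreVector:
    """RS = 1 + exp(-margin) per cell from a trained panel model.

    ``X`` is expression restricted (or restrictable via ``gene_names``)
    to the model's gene panel; missing panel genes raise an error naming
    them.  The margin excludes the offset ``b`` unless requested.
    """
    margin = model.margins(X, gene_names=gene_names, include_offset=include_offset)
    return RiskScoreVector(rs=1.0 + np.exp(-margin), margin=margin)


def _curve(values: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sens/spec over all midpoint thresholds, rule: value >= t is positive."""
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = np.sort(values[positive])
    neg = np.sort(values[~positive])
    n_pos, n_neg = len(pos), len(neg)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    return thresholds, sens, spec


def _auc(sens: np.ndarray, spec: np.ndarray) -> float:
    # sort by FPR then TPR so vertical curve segments integrate correctly
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    return float(np.trapezoid(sens[order], fpr[order]))


def roc_threshold(rs: RiskScoreVector, labels) -> ROCResult:
    """Calibrate the RS threshold separating embolic from non-embolic cells.

    The direction (whether high RS marks the embolic class) is chosen so
    that AUC >= 0.5; the threshold maximizes Youden J, ties resolving to
    the point of higher specificity.
    """
    labels = np.asarray(labels)
    positive = labels == 1
    if positive.all() or (~positive).all():
        raise ValueError("ROC needs both classes present")
    values = rs.rs
    if len(np.unique(values)) == 1:
        warnings.warn("all risk scores identical; ROC is degenerate",
                      stacklevel=2)
    thresholds, sens, spec = _curve(values, positive)
    auc = _auc(sens, spec)
    direction = "high_rs_embolic"
    if auc < 0.5:
        # flip: low RS marks the embolic class
        direction = "low_rs_embolic"
        t_neg, sens, spec = _curve(-values, positive)
        thresholds = -t_neg
        auc = _auc(sens, spec)
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    chosen = best[np.argmax(spec[best])]
    rs.orientation = direction
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        chosen_threshold=float(thresholds[chosen]),
        chosen_sens=float(sens[chosen]),
        chosen_spec=float(spec[chosen]),
        direction=direction,
    )


def classify_cells(rs: RiskScoreVector, threshold: float,
                   direction: str = "high_rs_embolic") -> np.ndarray:
    """Label cells +1 (embolic) / -1 by thresholding RS.

    Cells exactly at the threshold are called embolic (conservative).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction == "high_rs_embolic":
        emb = rs.rs >= threshold
    elif direction == "low_rs_embolic":
        emb = rs.rs <= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return np.where(emb, 1, -1)


def population_risk(cell_labels, dose_cells: float = 1e6,
                    calibration_frac: float = CALIBRATION_FRAC) -> RiskReport:
    """Population verdict: embolic_risk iff proportion >= calibration_frac.

    ``calibration_frac`` is an empirical, animal-model-derived constant
    (the pro-embolic fraction at which infusing ``dose_cells`` cells
    embolizes); it is configurable, not a property of the classifier.
    """
    labels = np.asarray(cell_labels)
    n = len(labels)
    n_pro = int((labels == 1).sum())
    return RiskReport(
        n_cells=n,
        n_proembolic=n_pro,
        proportion=n_pro / n,
        dose_cells=dose_cells,
        calibration_frac=calibration_frac,
    )
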