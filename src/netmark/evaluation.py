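"""ROC/AUC diagnostics, logistic biomarker panels, and planted-truth recovery.

AUC is the rank (Mann-Whitney U) statistic: the probability that a randomly
chosen case scores above a randomly chosen control, ties counting one half.
Score orientation is made explicit — a loss-of-expression marker whose levels
DROP in disease gets ``orientation='lower_is_case'`` and its AUC reported on
the flipped score, never silently.

A panel ("multiple biomarker") combines several genes' expression into one
diagnostic score by maximum-likelihood logistic regression (IRLS); perfectly
separating panels fall back to a weak ridge (1e-6) rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import (
    DegenerateLabelsError,
    FitFailureError,
    GeneLookupError,
    ValidationError,
)
from .synthetic import PlantedTruth

__all__ = [
    "ROCResult",
    "PanelModel",
    "auc_statistic",
    "roc_auc",
    "single_gene_diagnostics",
    "combine_biomarkers_logistic",
    "evaluate_recovery",
]


@dataclass
class ROCResult:
    """ROC curve with rank AUC and the score orientation that achieved it."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    orientation: str  # 'higher_is_case' or 'lower_is_case'

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class PanelModel:
    """Logistic multi-gene panel: coefficients and combined-score ROC."""

    genes: list[str]
    intercept: float
    coefficients: np.ndarray
    roc: ROCResult
    ridge: float = 0.0
    n_iter: int = 0


def _case_indicator(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    groups = set(np.unique(y).tolist())
    if not groups <= {"case", "control"}:
        raise ValidationError(f"labels must be case/control, got {sorted(groups)}")
    return y == "case"


def auc_statistic(scores, labels) -> float:
    """Raw (un-oriented) rank AUC = U/(n1*n0), ties credited one half."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    y = _case_indicator(labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("both classes required for ROC analysis")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, labels) -> ROCResult:
    """Oriented ROC curve and AUC (auc >= 0.5 after orientation selection)."""
    s = np.asarray(scores, dtype=float)
    y = _case_indicator(labels)
    auc = auc_statistic(s, y)
    if auc < 0.5:
        orientation = "lower_is_case"
        s_oriented, auc = -s, 1.0 - auc
    else:
        orientation = "higher_is_case"
        s_oriented = s
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s_oriented)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, orientation=orientation)


def single_gene_diagnostics(expr: pd.DataFrame, labels: pd.Series, gene: str) -> ROCResult:
    """ROC of one gene's expression as the diagnostic score."""
    if gene not in expr.index:
        raise GeneLookupError(f"gene {gene!r} not in the expression matrix")
    scores = expr.loc[gene].reindex(labels.index)
    if scores.isna().any():
        raise ValidationError("expression missing for some labeled samples")
    return roc_auc(scores.to_numpy(float), labels.to_numpy())


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, int, bool]:
    """Newton/IRLS for logistic regression; ridge is not applied to the intercept."""
    beta = np.zeros(X.shape[1])
    penalty = np.full(X.shape[1], ridge)
    penalty[0] = 0.0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        grad = X.T @ (y - p) - penalty * beta
        H = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, it, False
        beta = beta + step
        if not np.isfinite(beta).all():
            return beta, it, False
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            return beta, it, True
    return beta, max_iter, False


def combine_biomarkers_logistic(
    expr: pd.DataFrame, labels: pd.Series, genes: list[str]
) -> PanelModel:
    """Fit the multi-biomarker logistic panel and attach its combined-score ROC.

    Samples with missing expression in any listed gene are dropped (complete
    cases).  On separation or non-convergence the fit is repeated with a weak
    ridge (1e-6) on the gene coefficients; if that also fails a
    :class:`FitFailureError` carries the diagnostics.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("panel needs at least one gene")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise GeneLookupError(f"genes not in the expression matrix: {missing[:5]}")
    sub = expr.loc[genes].T.reindex(labels.index)
    complete = sub.notna().all(axis=1)
    sub, lab = sub.loc[complete], labels.loc[complete]
    y = _case_indicator(lab.to_numpy()).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateLabelsError("both classes required for the panel fit")

    X = np.column_stack([np.ones(len(sub)), sub.to_numpy(float)])
    beta, n_iter, ok = _irls(X, y, ridge=0.0)
    ridge_used = 0.0
    if not ok or not np.isfinite(beta).all() or np.abs(beta).max() > 1e6:
        beta, n_iter, ok = _irls(X, y, ridge=1e-6)
        ridge_used = 1e-6
        if not ok:
            raise FitFailureError(
                f"logistic panel failed to converge after {n_iter} iterations "
                f"(ridge {ridge_used}); |beta|max={np.abs(beta).max():.3g}"
            )
    linear = X @ beta
    roc = roc_auc(linear, lab.to_numpy())
    return PanelModel(
        genes=genes,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        roc=roc,
        ridge=ridge_used,
        n_iter=n_iter,
    )


def evaluate_recovery(
    scored: pd.DataFrame,
    truth: PlantedTruth,
    cutoff: float = 0.99,
) -> dict:
    """Score a ranked candidate table against planted biomarker truth.

    ``scored`` is the point table of :func:`netmark.model.score_nodes` (index
    node, column ``point``, already ranked).  Reports precision@k with
    k = number of planted biomarkers, recall at the probability cutoff, and
    the oriented rank AUC of the points against the planted labels.
    """
    if not truth.biomarker_nodes:
        raise ValidationError("planted truth contains no biomarkers")
    nodes = scored.index.to_numpy()
    is_bio = np.array([n in truth.biomarker_nodes for n in nodes])
    k = len(truth.biomarker_nodes)
    top_k = is_bio[:k].sum()
    points = scored["point"].to_numpy(float)
    recall = float(is_bio[points >= cutoff].sum()) / k
    if is_bio.any() and not is_bio.all():
        auc_raw = auc_statistic(points, is_bio)
        orientation = "higher_is_case" if auc_raw >= 0.5 else "lower_is_case"
        auc = max(auc_raw, 1.0 - auc_raw)
    else:
        auc_raw, auc, orientation = np.nan, np.nan, "undefined"
    return {
        "k": k,
        "n_scored": int(len(nodes)),
        "n_truth_scored": int(is_bio.sum()),
        "precision_at_k": float(top_k) / k,
        "recall_at_cutoff": recall,
        "cutoff": cutoff,
        "auc": float(auc),
        "auc_unoriented": float(auc_raw),
        "orientation": orientation,
        "prevalence": float(is_bio.mean()) if len(nodes) else np.nan,
    }
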