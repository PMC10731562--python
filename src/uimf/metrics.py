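"""Evaluation protocol for 3-class satisfaction prediction.

Confusion matrix (rows = true class, columns = predicted), per-class
precision/recall/F1 with a zero-on-zero-denominator convention, graded F1
(weighted mean of per-class F1 with weights (2, 1, 1) — the poor-satisfaction
class matters most clinically), accuracy, and Cohen's kappa, which corrects
agreement for chance and is the headline metric on the imbalanced corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "per_class_prf",
    "graded_f1",
    "cohen_kappa",
    "accuracy",
    "evaluate_predictions",
    "aggregate_reports",
]

GRADED_F1_WEIGHTS = (2.0, 1.0, 1.0)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (3, 3) ints, rows true, cols predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        rows[rows == 0] = 1.0
        return self.counts / rows


def confusion_matrix(true_labels, predicted_labels, n_classes: int = 3) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label lengths differ: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def per_class_prf(matrix: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision, recall, F1 per class; 0 wherever a denominator vanishes."""
    c = matrix.counts.astype(float)
    tp = np.diag(c)
    pred_tot = c.sum(axis=0)
    true_tot = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


def graded_f1(matrix: ConfusionMatrix, weights=GRADED_F1_WEIGHTS) -> float:
    """Weighted mean of per-class F1; weights (2,1,1) emphasize class 0."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    _, _, f1 = per_class_prf(matrix)
    return float(np.dot(weights, f1) / weights.sum())


def cohen_kappa(matrix: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    The degenerate single-cell matrix (p_e = p_o = 1) returns 0 by
    convention, since agreement cannot be distinguished from chance.
    """
    n = matrix.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = matrix.counts.astype(float)
    p_o = np.trace(c) / n
    p_e = float(np.dot(c.sum(axis=1), c.sum(axis=0))) / n**2
    if abs(1.0 - p_e) < 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def accuracy(matrix: ConfusionMatrix) -> float:
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix.counts) / matrix.total)


@dataclass
class EvalReport:
    """All comparison-protocol metrics derived from one confusion matrix."""

    matrix: ConfusionMatrix
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    graded_f1: float
    accuracy: float
    kappa: float
    n_evaluated: int
    empirical_risk: float | None = None
    train_seconds: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "confusion_counts": self.matrix.counts.tolist(),
            "confusion_rates": self.matrix.row_normalized().tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "graded_f1": self.graded_f1,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "n_evaluated": self.n_evaluated,
            "empirical_risk": self.empirical_risk,
            "train_seconds": self.train_seconds,
            "flags": self.flags,
        }


def evaluate_predictions(
    true_labels,
    predicted_labels,
    empirical_risk: float | None = None,
    train_seconds: float | None = None,
) -> EvalReport:
    """Build a full report from label pairs; all metrics share one matrix."""
    matrix = confusion_matrix(true_labels, predicted_labels)
    precision, recall, f1 = per_class_prf(matrix)
    flags = []
    if np.any(matrix.counts.sum(axis=0) == 0):
        flags.append("empty_predicted_class")
    return EvalReport(
        matrix=matrix,
        precision=precision,
        recall=recall,
        f1=f1,
        graded_f1=graded_f1(matrix),
        accuracy=accuracy(matrix),
        kappa=cohen_kappa(matrix),
        n_evaluated=matrix.total,
        empirical_risk=empirical_risk,
        train_seconds=train_seconds,
        flags=flags,
    )


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Mean +- sd of the headline metrics over cross-validation folds."""
    if not reports:
        raise ValueError("no reports to aggregate")

    def stats(values):
        a = np.asarray(values, dtype=float)
        return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0}

    out = {
        "graded_f1": stats([r.graded_f1 for r in reports]),
        "accuracy": stats([r.accuracy for r in reports]),
        "kappa": stats([r.kappa for r in reports]),
        "n_folds": len(reports),
    }
    times = [r.train_seconds for r in reports if r.train_seconds is not None]
    if times:
        out["train_seconds"] = stats(times)
    return out
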