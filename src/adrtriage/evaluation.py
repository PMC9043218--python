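"""Accuracy, per-class F1, and one-vs-rest multiclass ROC/AUC.

Works for any model exposing ``category_probabilities`` over the 5-level
causality scale, so the ordinal model and both baselines are compared along
the identical path.  Per-class ROC uses the predicted probability of that
class as the score (one-vs-rest); AUC is the concordance probability with
ties counted 1/2.  Classes absent from the truth have no defined ROC and are
excluded from the macro average (recorded as missing in the report); the
micro average pools the n x 5 binary indicator expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score, roc_curve

from .schema import ReportTable

__all__ = [
    "EvaluationReport",
    "accuracy",
    "f1_per_class",
    "roc_ovr",
    "auc_macro",
    "auc_micro",
    "evaluate_model",
]

CATEGORIES = (1, 2, 3, 4, 5)


@dataclass
class EvaluationReport:
    accuracy: float
    f1_by_class: dict[int, float]
    roc_by_class: dict[int, list[tuple[float, float]]]
    auc_by_class: dict[int, float | None]
    auc_macro: float
    auc_micro: float
    n_test: int
    class_counts: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "accuracy": self.accuracy,
            "f1_by_class": {str(k): v for k, v in self.f1_by_class.items()},
            "auc_by_class": {str(k): v for k, v in self.auc_by_class.items()},
            "auc_macro": self.auc_macro,
            "auc_micro": self.auc_micro,
            "n_test": self.n_test,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "roc_by_class": {
                str(k): [[float(a), float(b)] for a, b in v]
                for k, v in self.roc_by_class.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _check_lengths(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(truth)} truths")
    if len(pred) == 0:
        raise ValueError("empty inputs")
    return pred, truth


def accuracy(pred, truth) -> float:
    """Fraction of exact category matches."""
    pred, truth = _check_lengths(pred, truth)
    return float(np.mean(pred == truth))


def f1_per_class(pred, truth) -> dict[int, float]:
    """Harmonic mean of precision and recall per category.

    A category with neither predictions nor true occurrences scores 0,
    matching the convention of reporting 0 for unused categories.
    """
    pred, truth = _check_lengths(pred, truth)
    scores = f1_score(truth, pred, labels=list(CATEGORIES), average=None, zero_division=0.0)
    return {c: float(s) for c, s in zip(CATEGORIES, scores)}


def _check_probs(probs, truth):
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth)
    if probs.ndim != 2 or probs.shape[1] != len(CATEGORIES):
        raise ValueError("probs must be n x 5")
    if len(probs) != len(truth) or len(truth) == 0:
        raise ValueError("probs and truth must be equal non-zero length")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return probs, truth


def roc_ovr(probs, truth, cls: int) -> tuple[list[tuple[float, float]] | None, float | None]:
    """One-vs-rest ROC curve and AUC for one category.

    Returns ``(None, None)`` when the class is absent from the truth (or the
    truth is single-class), in which case the ROC is undefined.
    """
    probs, truth = _check_probs(probs, truth)
    y = (truth == cls).astype(int)
    if y.min() == y.max():
        return None, None
    score = probs[:, cls - 1]
    fpr, tpr, _ = roc_curve(y, score)
    auc = float(roc_auc_score(y, score))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def auc_macro(probs, truth) -> float:
    """Unweighted mean of defined per-class one-vs-rest AUCs."""
    probs, truth = _check_probs(probs, truth)
    aucs = [a for c in CATEGORIES if (a := roc_ovr(probs, truth, c)[1]) is not None]
    if not aucs:
        raise ValueError("no class has a defined ROC")
    return float(np.mean(aucs))


def auc_micro(probs, truth) -> float:
    """AUC of the pooled binary indicator expansion (n x 5 flattened)."""
    probs, truth = _check_probs(probs, truth)
    onehot = (truth[:, None] == np.array(CATEGORIES)[None, :]).astype(int)
    return float(roc_auc_score(onehot.ravel(), probs.ravel()))


def evaluate_model(model, test: ReportTable) -> EvaluationReport:
    """Full metric report for any model with ``category_probabilities``."""
    if len(test) == 0:
        raise ValueError("test table is empty")
    X = test.predictors()
    probs = np.asarray(model.category_probabilities(X), dtype=float)
    truth = test.labels()
    best = probs.max(axis=1, keepdims=True)
    pred = np.argmax(probs >= best - 1e-12, axis=1) + 1

    roc_by, auc_by = {}, {}
    for c in CATEGORIES:
        curve, auc = roc_ovr(probs, truth, c)
        auc_by[c] = auc
        if curve is not None:
            roc_by[c] = curve
    return EvaluationReport(
        accuracy=accuracy(pred, truth),
        f1_by_class=f1_per_class(pred, truth),
        roc_by_class=roc_by,
        auc_by_class=auc_by,
        auc_macro=auc_macro(probs, truth),
        auc_micro=auc_micro(probs, truth),
        n_test=len(test),
        class_counts={c: int(np.sum(truth == c)) for c in CATEGORIES},
    )
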