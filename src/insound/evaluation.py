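"""Macro-averaged multiclass evaluation.

The metric suite reports the confusion matrix, top-1 accuracy, macro recall,
macro precision, macro F1 and macro one-vs-rest AUC, all as percentages to
two decimals.  Macro averaging weights every class equally regardless of
prevalence, which is the right convention when each species matters on its
own.  Note the F1 convention: macro-F1 here is the harmonic mean of
macro-precision and macro-recall (not the mean of per-class F1 scores); a
``convention`` flag switches to the per-class-average reading.

On a balanced n-class test set a degenerate constant predictor lands at the
analytic collapse point: accuracy = recall = 100/n, macro-F1 =
2 (1/n^2 * 1/n) / (1/n^2 + 1/n) * 100, and AUC = 50 for uninformative
scores — for 12 classes: 8.33, 1.28 and 50.00.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "accuracy_at_1",
    "macro_prf",
    "macro_auc",
    "evaluate",
    "crossval_summary",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts matrix: cell (i, j) = number of samples with true i predicted j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) and (min(y_true.min(), y_pred.min()) < 0 or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels out of range")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def accuracy_at_1(y_true, scores) -> float:
    """Percentage of samples whose top-scoring class is the true class.

    Ties in a score row resolve to the lowest class index (argmax convention).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if len(y_true) == 0:
        raise ValueError("empty input")
    pred = scores.argmax(axis=1) if scores.ndim == 2 else scores
    return float(np.mean(pred == y_true) * 100.0)


def macro_prf(y_true, y_pred, convention: str = "macro_harmonic") -> tuple[float, float, float]:
    """Macro recall, macro precision and macro F1, in percent.

    Per-class recall/precision are averaged unweighted over the classes
    present in ``y_true`` (classes with no true samples are excluded with a
    warning; a class never predicted gets precision 0).  With
    ``convention="macro_harmonic"`` (default) F1 is the harmonic mean of the
    two macro averages; ``"per_class"`` averages per-class F1 instead.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    absent = [int(c) for c in classes if not np.any(y_true == c)]
    if absent:
        warnings.warn(f"classes {absent} have no true samples; excluded from macro averages")
    present = [c for c in classes if np.any(y_true == c)]
    recalls, precisions, f1s = [], [], []
    for c in present:
        tp = np.sum((y_true == c) & (y_pred == c))
        recall = tp / np.sum(y_true == c)
        n_pred = np.sum(y_pred == c)
        precision = tp / n_pred if n_pred else 0.0
        recalls.append(recall)
        precisions.append(precision)
        f1s.append(2 * precision * recall / (precision + recall) if precision + recall else 0.0)
    mr, mp = float(np.mean(recalls)), float(np.mean(precisions))
    if convention == "macro_harmonic":
        f1 = 2 * mp * mr / (mp + mr) if mp + mr else 0.0
    elif convention == "per_class":
        f1 = float(np.mean(f1s))
    else:
        raise ValueError("convention must be 'macro_harmonic' or 'per_class'")
    return mr * 100.0, mp * 100.0, f1 * 100.0


def macro_auc(y_true, scores) -> float:
    """Unweighted mean of one-vs-rest AUCs, in percent (mid-rank ties).

    Classes absent from ``y_true`` are excluded with a warning; constant
    scores give exactly 50.00.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    present = np.unique(y_true)
    if len(present) < 2 and scores.shape[1] > 1:
        warnings.warn("fewer than two classes present; AUC undefined, returning nan")
        return float("nan")
    absent = [c for c in range(scores.shape[1]) if c not in present]
    if absent:
        warnings.warn(f"classes {absent} have no true samples; excluded from macro AUC")
    aucs = []
    for c in present:
        aucs.append(_sk_auc((y_true == c).astype(int), scores[:, c]))
    return float(np.mean(aucs) * 100.0)


@dataclass
class EvalReport:
    """Full metric bundle for one evaluation split."""

    confusion: np.ndarray
    accuracy_at_1: float
    macro_recall: float
    macro_precision: float
    macro_f1: float
    macro_auc: float
    per_class: pd.DataFrame
    n_eval: int
    class_names: list[str] = field(default_factory=list)

    @property
    def confusion_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, self.confusion / rows, 0.0)

    def summary(self) -> dict:
        return {
            "n_eval": self.n_eval,
            "accuracy_at_1": round(self.accuracy_at_1, 2),
            "macro_recall": round(self.macro_recall, 2),
            "macro_precision": round(self.macro_precision, 2),
            "macro_f1": round(self.macro_f1, 2),
            "macro_auc": round(self.macro_auc, 2),
        }

    def save(self, prefix: str) -> None:
        """Emit JSON summary, per-class CSV, confusion CSV and a heat-map PNG."""
        with open(f"{prefix}_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        self.per_class.to_csv(f"{prefix}_per_class.csv", index=False)
        pd.DataFrame(self.confusion).to_csv(f"{prefix}_confusion.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion_normalized, cmap="Blues", vmin=0, vmax=1)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(f"{prefix}_confusion.png", dpi=100)
        plt.close(fig)


def evaluate(y_true, scores, class_names: list[str] | None = None) -> EvalReport:
    """Score a split: probability rows per sample against integer labels."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if scores.ndim != 2 or len(scores) != len(y_true):
        raise ValueError("scores must be one probability row per sample")
    n_classes = scores.shape[1]
    y_pred = scores.argmax(axis=1)
    conf = confusion_matrix(y_true, y_pred, n_classes)
    mr, mp, f1 = macro_prf(y_true, y_pred)
    rows = []
    for c in range(n_classes):
        tp = conf[c, c]
        n_true = conf[c].sum()
        n_pred = conf[:, c].sum()
        rows.append(
            {
                "class": class_names[c] if class_names else c,
                "n_true": int(n_true),
                "recall_pct": round(100.0 * tp / n_true, 2) if n_true else np.nan,
                "precision_pct": round(100.0 * tp / n_pred, 2) if n_pred else 0.0,
            }
        )
    return EvalReport(
        confusion=conf,
        accuracy_at_1=accuracy_at_1(y_true, scores),
        macro_recall=mr,
        macro_precision=mp,
        macro_f1=f1,
        macro_auc=macro_auc(y_true, scores),
        per_class=pd.DataFrame(rows),
        n_eval=len(y_true),
        class_names=class_names or [],
    )


def crossval_summary(reports: list[EvalReport]) -> pd.DataFrame:
    """Mean +/- unbiased std per metric over k folds, formatted to 2 decimals."""
    if len(reports) < 2:
        raise ValueError("need at least two folds")
    metrics = ["accuracy_at_1", "macro_recall", "macro_precision", "macro_f1", "macro_auc"]
    rows = []
    for m in metrics:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        mean, std = float(vals.mean()), float(vals.std(ddof=1))
        rows.append({"metric": m, "mean": mean, "std": std, "formatted": f"{mean:.2f}±{std:.2f}"})
    return pd.DataFrame(rows)
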