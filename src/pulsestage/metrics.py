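"""Evaluation: confusion matrix, one-vs-rest precision/recall/F1, ROC AUC,
fold-wise accuracy confidence intervals, and the one-way ANOVA input
comparison.

Per-class scores collapse the 5x5 confusion matrix one-vs-rest: for class c,
TP is the diagonal entry, FP the rest of its column, FN the rest of its row.
Overall accuracy is trace/total — the multiclass reading of the binary
accuracy formula (the two coincide only for two classes).  Macro averages are
unweighted means over the five classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

from .preprocess import CLASS_ORDER

#: z quantile for a 95% normal interval.
Z_95 = 1.9600


@dataclass
class ConfusionMatrix:
    """5x5 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: list = field(default_factory=lambda: [c.value for c in CLASS_ORDER])

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc_per_class: Optional[np.ndarray] = None
    macro_auc: Optional[float] = None
    accuracy_ci: Optional[tuple] = None


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 5) -> ConfusionMatrix:
    """Confusion matrix over integer class codes in the fixed class order."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"unknown label in {name}")
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts=cm)


def classification_scores(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy (trace/total) and one-vs-rest precision/recall/F1 per class.

    Zero-denominator cases (a class never predicted, or with no support)
    score 0 with a warning.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    if np.any(tp + fp == 0) or np.any(tp + fn == 0):
        warnings.warn("zero-denominator class scored as 0", UserWarning)
    return EvalReport(
        accuracy=float(np.trace(counts) / total),
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def roc_auc_ovr(y_true: Sequence[int], probs: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class one-vs-rest AUC (trapezoidal, midpoint tie handling) + macro.

    Classes with no positives (or no negatives) have undefined AUC (nan) and
    are excluded from the macro mean with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != y_true.size:
        raise ValueError("probs must be (n, n_classes) aligned with y_true")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    K = probs.shape[1]
    aucs = np.full(K, np.nan)
    for c in range(K):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"AUC undefined for class {c} (no positives or no negatives)", UserWarning)
            continue
        aucs[c] = roc_auc_score(pos.astype(int), probs[:, c])
    defined = np.isfinite(aucs)
    macro = float(aucs[defined].mean()) if defined.any() else float("nan")
    return aucs, macro


def roc_coordinates(y_true: Sequence[int], probs: np.ndarray, n_classes: int = 5):
    """One-vs-rest (FPR, TPR) coordinate arrays per class, for plotting."""
    y_true = np.asarray(y_true, dtype=int)
    out = {}
    for c in range(n_classes):
        pos = (y_true == c).astype(int)
        if pos.any() and not pos.all():
            fpr, tpr, _ = roc_curve(pos, probs[:, c])
            out[c] = (fpr, tpr)
    return out


def accuracy_ci(fold_accuracies: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval over fold-model test accuracies.

    mean +- z * s / sqrt(k) with the sample standard deviation (ddof=1),
    z = 1.9600 at 95%, clipped to [0, 1].
    """
    accs = np.asarray(fold_accuracies, dtype=float)
    if accs.size < 2:
        raise ValueError("need at least 2 fold accuracies")
    if level == 0.95:
        z = Z_95
    else:
        z = float(stats.norm.ppf(0.5 + level / 2.0))
    mean = accs.mean()
    half = z * accs.std(ddof=1) / np.sqrt(accs.size)
    return float(np.clip(mean - half, 0.0, 1.0)), float(np.clip(mean + half, 0.0, 1.0))


def accuracy_ci_bootstrap(fold_accuracies: Sequence[float], level: float = 0.95,
                          n_boot: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Percentile-bootstrap alternative to the normal interval."""
    accs = np.asarray(fold_accuracies, dtype=float)
    if accs.size < 2:
        raise ValueError("need at least 2 fold accuracies")
    rng = np.random.default_rng(seed)
    means = rng.choice(accs, size=(n_boot, accs.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 0.5 + level / 2])
    return float(lo), float(hi)


def anova_input_comparison(grouped_values: dict) -> tuple[float, float]:
    """One-way ANOVA across groups (e.g. per-fold test accuracies per input mode).

    Returns (F, p) with (g-1, N-g) degrees of freedom.  If every value in
    every group is identical the decomposition is degenerate; (0, 1) is
    returned.
    """
    groups = [np.asarray(v, dtype=float) for v in grouped_values.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def anova_feature_by_class(segments) -> tuple[float, float]:
    """Feature-significance reading of the ANOVA: mean segment amplitude
    (PPG+ECG averaged) grouped by the five blood-pressure labels."""
    from .preprocess import CLASS_ORDER as order

    grouped = {}
    for lab in order:
        vals = [float(np.mean([s.ppg.mean(), s.ecg.mean()])) for s in segments if s.label is lab]
        if len(vals) >= 2:
            grouped[lab.value] = vals
    return anova_input_comparison(grouped)


def evaluate_predictions(y_true, y_pred, probs=None, fold_accuracies=None) -> EvalReport:
    """Bundle confusion-derived scores, optional AUC and optional fold CI."""
    report = classification_scores(confusion(y_true, y_pred))
    if probs is not None:
        report.auc_per_class, report.macro_auc = roc_auc_ovr(y_true, probs)
    if fold_accuracies is not None:
        report.accuracy_ci = accuracy_ci(fold_accuracies)
    return report
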