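"""Classification metrics from a K-class confusion matrix or scores.

The confusion matrix convention is rows = actual label, columns =
predicted label.  Per-class rates are computed one-vs-rest; single
numbers for multiclass problems are unweighted (macro) averages over the
classes.  Division-by-zero cases (e.g. precision with no predicted
positives) return 0 and raise a flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix_from_labels",
    "per_class_rates",
    "kappa_mcc",
    "error_scores",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows actual, columns predicted
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.size == 0:
            raise ValueError("confusion matrix must be non-empty")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class k against the rest."""
        c = self.counts
        tp = int(c[k, k])
        fn = int(c[k].sum() - tp)
        fp = int(c[:, k].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, tn, fp, fn


@dataclass
class MetricReport:
    per_class: pd.DataFrame  # acc, recall, specificity, precision, f1, fpr, fnr, fdr
    macro: dict[str, float]
    flags: list[str] = field(default_factory=list)


def confusion_matrix_from_labels(actual, predicted, labels) -> ConfusionMatrix:
    labels = list(labels)
    index = {lbl: i for i, lbl in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: 0/0 treated as 0")
        return 0.0
    return num / den


def per_class_rates(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest accuracy, recall, specificity, precision, F1, FPR,
    FNR and FDR per class, plus their macro averages."""
    if cm.total == 0:
        raise ValueError("confusion matrix has no samples")
    k = cm.counts.shape[0]
    flags: list[str] = []
    rows = []
    for i in range(k):
        tp, tn, fp, fn = cm.one_vs_rest(i)
        name = cm.labels[i] if cm.labels else str(i)
        recall = _safe_div(tp, tp + fn, f"recall[{name}]", flags)
        precision = _safe_div(tp, tp + fp, f"precision[{name}]", flags)
        rows.append(
            {
                "class": name,
                "acc": (tp + tn) / cm.total,
                "recall": recall,
                "specificity": _safe_div(tn, tn + fp, f"specificity[{name}]", flags),
                "precision": precision,
                "f1": _safe_div(
                    2 * precision * recall, precision + recall, f"f1[{name}]", flags
                ),
                "fpr": _safe_div(fp, fp + tn, f"fpr[{name}]", flags),
                "fnr": _safe_div(fn, fn + tp, f"fnr[{name}]", flags),
                "fdr": _safe_div(fp, tp + fp, f"fdr[{name}]", flags),
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    macro = per_class.mean().to_dict()
    macro["overall_acc"] = float(np.trace(cm.counts) / cm.total)
    return MetricReport(per_class=per_class, macro=macro, flags=flags)


def kappa_mcc(cm: ConfusionMatrix) -> tuple[float, float]:
    """Cohen's kappa and the multiclass Matthews correlation (R_K).

    Both compare observed agreement against the chance level implied by
    the marginals; degenerate single-class matrices return 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix has no samples")
    c = cm.counts.astype(np.float64)
    n = c.sum()
    p_obs = np.trace(c) / n
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    p_exp = float(row @ col) / n**2
    kappa = 0.0 if p_exp == 1.0 else (p_obs - p_exp) / (1.0 - p_exp)

    cov_xy = np.trace(c) * n - float(row @ col)
    cov_xx = n**2 - float(col @ col)
    cov_yy = n**2 - float(row @ row)
    denom = np.sqrt(cov_xx * cov_yy)
    mcc = 0.0 if denom == 0 else cov_xy / denom
    return float(kappa), float(mcc)


def error_scores(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """MAE and RMSE over all (sample, class) probability terms.

    ``actual`` holds one-hot vectors, ``predicted`` probability vectors of
    the same shape.
    """
    actual = np.asarray(actual, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted shapes differ")
    if predicted.min() < 0 or predicted.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    diff = actual - predicted
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    return mae, rmse


def _binary_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by threshold sweep over the distinct scores, trapezoid rule."""
    order = np.argsort(-scores, kind="stable")
    y = y[order]
    s = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return float(np.trapezoid(tpr, fpr))


def roc_auc(
    actual, scores: np.ndarray, labels=None
) -> tuple[dict[str, float], float, list[str]]:
    """One-vs-rest ROC AUC per class and its macro average.

    ``scores`` is (n_samples, K) with per-class probabilities.  A class
    without both positives and negatives is skipped with a flag.
    """
    scores = np.asarray(scores, dtype=np.float64)
    actual = np.asarray(actual)
    if labels is None:
        labels = sorted(set(actual))
    if scores.shape[1] != len(labels):
        raise ValueError("score columns must match the label list")
    flags: list[str] = []
    aucs: dict[str, float] = {}
    for j, lbl in enumerate(labels):
        y = (actual == lbl).astype(np.int64)
        if y.sum() == 0 or y.sum() == len(y):
            flags.append(f"auc[{lbl}]: skipped, single-class ground truth")
            continue
        aucs[str(lbl)] = _binary_auc(y, scores[:, j])
    if not aucs:
        raise ValueError("no class had both positive and negative samples")
    macro = float(np.mean(list(aucs.values())))
    return aucs, macro, flags
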