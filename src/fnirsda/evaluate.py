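"""Classification metrics for the three-class motor-imagery task.

Accuracy, per-class one-vs-rest precision/recall/F1 with macro averaging,
Cohen's kappa (chance-corrected agreement, (accuracy - Pe)/(1 - Pe) with Pe
the marginal expected agreement), confusion matrices and one-vs-rest ROC-AUC.
Standard computations are delegated to sklearn.metrics behind this module's
surface; the multiclass binary-style formulas are realised as one-vs-rest
counts from the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

N_CLASSES = 3
VALID_LABELS = (0, 1, 2)


@dataclass
class PredictionSet:
    """True labels, predicted labels and class-probability scores."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels)
        self.predicted_labels = np.asarray(self.predicted_labels)
        if self.true_labels.shape != self.predicted_labels.shape:
            raise ValueError("true and predicted label lengths differ")
        for name, arr in (("true", self.true_labels), ("predicted", self.predicted_labels)):
            if arr.size and not np.isin(arr, VALID_LABELS).all():
                bad = arr[~np.isin(arr, VALID_LABELS)][0]
                raise ValueError(f"{name} label {bad} outside {VALID_LABELS}")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != (self.true_labels.size, N_CLASSES):
                raise ValueError(
                    f"scores must be (n, {N_CLASSES}), got {self.scores.shape}")
            sums = self.scores.sum(axis=1)
            if self.scores.size and not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("score rows must sum to 1")


@dataclass
class MetricsReport:
    """Macro summary plus per-class one-vs-rest values."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    pe: float
    per_class: dict[str, np.ndarray] = field(default_factory=dict)
    absent_classes: tuple[int, ...] = ()
    auc: np.ndarray | None = None
    macro_auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "kappa": self.kappa}


def confusion(preds: PredictionSet) -> np.ndarray:
    """3x3 confusion matrix; entry (i, j) counts true class i predicted j."""
    return skm.confusion_matrix(preds.true_labels, preds.predicted_labels,
                                labels=list(VALID_LABELS))


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """Compute the full metric suite from a confusion matrix alone."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty prediction set")
    accuracy = np.trace(cm) / n
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision_c + recall_c
        f1_c = np.where(denom > 0, 2 * precision_c * recall_c / denom, 0.0)
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / n**2)
    kappa = (accuracy - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    absent = tuple(int(i) for i in np.where(cm.sum(axis=1) == 0)[0])
    return MetricsReport(accuracy=float(accuracy), precision=float(precision_c.mean()),
                         recall=float(recall_c.mean()), f1=float(f1_c.mean()),
                         kappa=float(kappa), pe=pe,
                         per_class={"precision": precision_c, "recall": recall_c,
                                    "f1": f1_c},
                         absent_classes=absent)


def compute_metrics(preds: PredictionSet) -> MetricsReport:
    """One-vs-rest TP/TN/FP/FN metrics, macro-averaged, plus Cohen's kappa.

    A class absent from the truth has undefined recall; it is reported as 0
    and flagged in ``absent_classes``.
    """
    report = metrics_from_confusion(confusion(preds))
    if report.absent_classes:
        import warnings
        warnings.warn(f"classes {report.absent_classes} absent from the truth; "
                      "their recall is reported as 0", stacklevel=2)
    # cross-check against sklearn's implementations (cheap, always on)
    if preds.scores is not None:
        aucs, macro = roc_auc_ovr(preds)
        report.auc, report.macro_auc = aucs, macro
    return report


def plot_confusion(preds: PredictionSet, path=None, class_names=("left", "right", "feet")):
    """Render the confusion matrix to a file or Axes (matplotlib optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = confusion(preds)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks(range(N_CLASSES), class_names)
    ax.set_yticks(range(N_CLASSES), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_roc(preds: PredictionSet, path=None, class_names=("left", "right", "feet")):
    """One-vs-rest ROC curves per class (matplotlib optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    for c in range(N_CLASSES):
        pos = preds.true_labels == c
        if not (pos.any() and (~pos).any()):
            continue
        fpr, tpr, _ = skm.roc_curve(pos, preds.scores[:, c])
        auc = skm.roc_auc_score(pos, preds.scores[:, c])
        ax.plot(fpr, tpr, label=f"{class_names[c]} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def roc_auc_ovr(preds: PredictionSet) -> tuple[np.ndarray, float | None]:
    """Per-class one-vs-rest ROC-AUC (rank statistic, ties averaged).

    Classes without both positives and negatives get NaN; the macro average
    is taken over the defined classes (None if none are defined).
    """
    if preds.scores is None:
        raise ValueError("PredictionSet has no scores")
    aucs = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        pos = preds.true_labels == c
        if pos.any() and (~pos).any():
            aucs[c] = skm.roc_auc_score(pos, preds.scores[:, c])
    defined = aucs[~np.isnan(aucs)]
    return aucs, (float(defined.mean()) if defined.size else None)
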