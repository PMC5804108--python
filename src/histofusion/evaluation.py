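"""Evaluation: softmax classification of reduced features, confusion matrix
with precision/recall margins, one-vs-rest ROC curves, per-class and mean
AUC, and the three-arm comparison report (coding network vs MPCA vs MSAE).

Conventions: labels are 1-based integers 1..C; prediction is the argmax of
the class-probability row with ties broken toward the lower class index;
per-class "accuracy" in the comparison report is per-class recall
(diagonal count / true count of the class); mean AUC is the unweighted
average of the C one-vs-rest AUCs (class-frequency weighting optional).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .synthetic import ConfigurationError


class DataError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclasses.dataclass
class EvalReport:
    confusion: np.ndarray  # C x C counts, rows = true, cols = predicted
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_accuracy: np.ndarray  # alias of recall (diagonal / row total)
    overall_accuracy: float
    roc_points: list  # per class: list of (fpr, tpr)
    per_class_auc: np.ndarray
    mean_auc: float
    empty_prediction_classes: tuple = ()  # classes never predicted (precision 0)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "roc_points": [[list(map(float, p)) for p in pts] for pts in self.roc_points],
            "per_class_auc": self.per_class_auc.tolist(),
            "mean_auc": self.mean_auc,
            "empty_prediction_classes": list(self.empty_prediction_classes),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def train_softmax_classifier(X, y, cfg: dict | None = None, seed: int = 0):
    """Multinomial logistic (softmax) classifier minimizing cross-entropy.

    Thin wrapper over scikit-learn's LogisticRegression (lbfgs), which is
    deterministic for a fixed input; ``seed`` is accepted for interface
    symmetry with the stochastic trainers."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("need at least two classes present in y")
    cfg = cfg or {}
    clf = LogisticRegression(
        C=cfg.get("C", 10.0),
        max_iter=cfg.get("max_iter", 2000),
        tol=cfg.get("tol", 1e-6),
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def predict_argmax(scores: np.ndarray) -> np.ndarray:
    """1-based argmax prediction; ties go to the lower class index."""
    return np.argmax(scores, axis=1) + 1


def confusion_counts(y_true, y_pred, C: int):
    """C x C counts plus precision/recall margins.

    precision_j = confusion[j][j] / column-sum_j (0, flagged, if class j is
    never predicted); recall_i = confusion[i][i] / row-sum_i."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for arr, name in [(y_true, "y_true"), (y_pred, "y_pred")]:
        if arr.min() < 1 or arr.max() > C:
            raise DataError(f"{name} labels outside 1..{C}")
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(1, C + 1))
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    empty = tuple(int(j + 1) for j in np.flatnonzero(col == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
    return cm, precision, recall, empty


def roc_one_vs_rest(scores: np.ndarray, y, c: int) -> list[tuple[float, float]]:
    """ROC points for class ``c`` vs the rest, sweeping the threshold over
    that class's probability column.  Tied scores are grouped (one point per
    distinct score); the curve is anchored at (0,0) and (1,1)."""
    y = np.asarray(y)
    if c not in y:
        raise DataError(f"class {c} absent from y")
    col = np.asarray(scores)[:, c - 1]
    fpr, tpr, _ = _sk_roc_curve(y == c, col, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def auc(points) -> float:
    """Trapezoidal area under an anchored, fpr-sorted ROC point list."""
    fpr = np.asarray([p[0] for p in points], dtype=float)
    tpr = np.asarray([p[1] for p in points], dtype=float)
    if np.any(np.diff(fpr) < 0):
        raise ContractError("ROC points must be sorted by fpr")
    if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
        raise ContractError("ROC points must be anchored at (0,0) and (1,1)")
    return float(np.trapezoid(tpr, fpr))


def evaluate(scores: np.ndarray, y_true, C: int | None = None) -> EvalReport:
    """Full evaluation report from a class-probability matrix."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y_true = np.asarray(y_true)
    if C is None:
        C = scores.shape[1]
    y_pred = predict_argmax(scores)
    cm, precision, recall, empty = confusion_counts(y_true, y_pred, C)
    overall = float(np.trace(cm) / cm.sum())
    roc_points, aucs = [], []
    for c in range(1, C + 1):
        if c in y_true:
            pts = roc_one_vs_rest(scores, y_true, c)
            roc_points.append(pts)
            aucs.append(auc(pts))
        else:  # class absent from this test split: no curve is defined
            roc_points.append([])
            aucs.append(np.nan)
    aucs = np.asarray(aucs)
    return EvalReport(
        confusion=cm,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_accuracy=recall,
        overall_accuracy=overall,
        roc_points=roc_points,
        per_class_auc=aucs,
        mean_auc=float(np.nanmean(aucs)),
        empty_prediction_classes=empty,
    )


def mean_auc(report: EvalReport, weights: np.ndarray | None = None) -> float:
    """Unweighted by default; pass class frequencies for a weighted mean."""
    if weights is None:
        return float(np.nanmean(report.per_class_auc))
    w = np.asarray(weights, dtype=float)
    ok = ~np.isnan(report.per_class_auc)
    return float(np.sum(report.per_class_auc[ok] * w[ok]) / np.sum(w[ok]))


def compare_pipelines(results: dict[str, EvalReport], y_true=None) -> dict:
    """Comparison table across arms: overall accuracy, per-class accuracy
    and mean AUC per arm.  All arms must have been evaluated on the same
    test split (same confusion totals and row margins)."""
    if not results:
        raise ContractError("no arms to compare")
    row_margins = {k: r.confusion.sum(axis=1) for k, r in results.items()}
    first = next(iter(row_margins.values()))
    for k, marg in row_margins.items():
        if marg.shape != first.shape or not np.array_equal(marg, first):
            raise ContractError(f"arm {k!r} evaluated on a different test set")
    return {
        "overall_accuracy": {k: r.overall_accuracy for k, r in results.items()},
        "per_class_accuracy": {
            k: r.per_class_accuracy.tolist() for k, r in results.items()
        },
        "mean_auc": {k: r.mean_auc for k, r in results.items()},
    }


def comparison_markdown(table: dict) -> str:
    arms = list(table["overall_accuracy"])
    C = len(next(iter(table["per_class_accuracy"].values())))
    lines = ["| metric | " + " | ".join(arms) + " |"]
    lines.append("|---" * (len(arms) + 1) + "|")
    lines.append(
        "| overall accuracy | "
        + " | ".join(f"{table['overall_accuracy'][a]:.1%}" for a in arms)
        + " |"
    )
    for c in range(C):
        lines.append(
            f"| class {c + 1} accuracy | "
            + " | ".join(f"{table['per_class_accuracy'][a][c]:.1%}" for a in arms)
            + " |"
        )
    lines.append(
        "| mean AUC | "
        + " | ".join(f"{table['mean_auc'][a]:.4f}" for a in arms)
        + " |"
    )
    return "\n".join(lines)


def plot_confusion(report: EvalReport, path) -> None:
    """Confusion-matrix figure with precision/recall margins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion
    C = cm.shape[0]
    fig, ax = plt.subplots(figsize=(1.1 * C + 2, 1.1 * C + 2))
    grid = np.zeros((C + 1, C + 1))
    grid[:C, :C] = cm
    ax.imshow(grid == 0, cmap="Greys", alpha=0.1)
    for i in range(C):
        for j in range(C):
            color = "#b9eec2" if i == j else ("#f6c3cb" if cm[i, j] else "white")
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, color=color))
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
        ax.text(C, i, f"{report.per_class_recall[i]:.1%}", ha="center", va="center")
        ax.text(i, C, f"{report.per_class_precision[i]:.1%}", ha="center", va="center")
    ax.text(C, C, f"{report.overall_accuracy:.1%}", ha="center", va="center",
            fontweight="bold")
    ax.set_xticks(range(C + 1))
    ax.set_xticklabels([f"T{j + 1}" for j in range(C)] + ["recall"])
    ax.set_yticks(range(C + 1))
    ax.set_yticklabels([f"T{i + 1}" for i in range(C)] + ["precision"])
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    ax.set_xlim(-0.5, C + 0.5)
    ax.set_ylim(C + 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_roc(report: EvalReport, path) -> None:
    """One-vs-rest ROC curves for every class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, pts in enumerate(report.roc_points, start=1):
        if not pts:
            continue
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        ax.plot(fpr, tpr, label=f"T{c} (AUC {report.per_class_auc[c - 1]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
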