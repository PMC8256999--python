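"""Evaluation metrics: confusion matrix, precision/recall/F1, one-vs-rest ROC AUC.

All metrics are computed from first principles (counting and trapezoidal
integration); presentation values are rounded to two decimals with ties
away from zero, so an accuracy of 0.925 prints as 0.93.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .polarimetry import CLASS_LABELS

__all__ = [
    "round_half_away",
    "confusion",
    "precision_recall_f1",
    "accuracy",
    "roc_auc_ovr",
    "render_report",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties away from zero (0.925 -> 0.93)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_labels(labels, classes) -> None:
    unknown = set(map(str, labels)) - set(map(str, classes))
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")


def confusion(true_labels, predicted_labels, classes=CLASS_LABELS) -> pd.DataFrame:
    """k x k confusion matrix; rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    _check_labels(true_labels, classes)
    _check_labels(predicted_labels, classes)
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        cm.loc[str(t), str(p)] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(cm: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest precision, recall and F1 per class from a confusion matrix.

    For class c: TP = cm[c, c], FP = column sum - TP, FN = row sum - TP;
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.
    Returns raw values plus 2-decimal presentation columns.
    """
    rows = []
    for c in cm.index:
        tp = float(cm.loc[c, c])
        fp = float(cm[c].sum() - tp)
        fn = float(cm.loc[c].sum() - tp)
        precision = _safe_ratio(tp, tp + fp, f"precision of {c}")
        recall = _safe_ratio(tp, tp + fn, f"recall of {c}")
        f1 = _safe_ratio(2 * precision * recall, precision + recall, f"F1 of {c}")
        rows.append(
            {
                "class": c,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "precision_2dp": round_half_away(precision),
                "recall_2dp": round_half_away(recall),
                "f1_2dp": round_half_away(f1),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def accuracy(cm: pd.DataFrame) -> float:
    """Overall accuracy: trace / total count."""
    total = cm.to_numpy().sum()
    if total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.to_numpy()) / total)


def _binary_auc(pos: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal AUC of a one-vs-rest ROC, thresholds at distinct scores.

    Equivalent to the Mann-Whitney statistic with ties counted 1/2.
    """
    order = np.argsort(-scores, kind="stable")
    pos = pos[order]
    scores = scores[order]
    # group tied scores: cumulative TP/FP at each distinct threshold
    distinct = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], dtype=int)
    cut = np.append(distinct, scores.size - 1)
    tp = np.cumsum(pos)[cut]
    fp = np.cumsum(1 - pos)[cut]
    n_pos, n_neg = tp[-1], fp[-1]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def roc_auc_ovr(true_labels, scores, classes=CLASS_LABELS) -> dict:
    """Per-class one-vs-rest AUC and their unweighted mean.

    ``scores`` is an (n, k) array of class scores (vote fractions), columns
    following ``classes``.  Classes absent from the true labels get a
    missing (NaN) AUC and are excluded from the mean with a warning.
    """
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=float)
    _check_labels(true_labels, classes)
    if scores.shape != (true_labels.size, len(classes)):
        raise ValueError(f"scores must be shaped (n, {len(classes)})")
    aucs: dict[str, float] = {}
    for j, c in enumerate(classes):
        pos = (true_labels == c).astype(float)
        if pos.sum() == 0 or pos.sum() == pos.size:
            warnings.warn(
                f"class {c!r} has no positives/negatives in the true labels; AUC undefined",
                stacklevel=2,
            )
            aucs[str(c)] = float("nan")
            continue
        aucs[str(c)] = _binary_auc(pos, scores[:, j])
    defined = [v for v in aucs.values() if not np.isnan(v)]
    aucs["mean"] = float(np.mean(defined)) if defined else float("nan")
    return aucs


def render_report(
    out_dir,
    cm: pd.DataFrame,
    metrics: pd.DataFrame,
    aucs: dict,
    importance: np.ndarray,
    feature_names,
) -> dict[str, Path]:
    """Write the evaluation artifacts of one run into ``out_dir``.

    Files: confusion.csv, metrics.csv, auc.csv, importance.csv (descending
    ranking), importance_matrix.csv (4x4 layout, m11 slot marked as the
    normalization element), summary.log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["confusion"] = out / "confusion.csv"
    cm.to_csv(paths["confusion"])

    paths["metrics"] = out / "metrics.csv"
    metrics.to_csv(paths["metrics"])

    paths["auc"] = out / "auc.csv"
    pd.DataFrame([aucs]).to_csv(paths["auc"], index=False)

    ranking = (
        pd.DataFrame({"feature": list(feature_names), "importance": np.asarray(importance)})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    paths["importance"] = out / "importance.csv"
    ranking.to_csv(paths["importance"], index=False)

    by_name = dict(zip(feature_names, np.asarray(importance)))
    grid = [
        [
            "norm" if (i, j) == (1, 1) else f"{by_name.get(f'm{i}{j}', float('nan')):.4f}"
            for j in range(1, 5)
        ]
        for i in range(1, 5)
    ]
    paths["importance_matrix"] = out / "importance_matrix.csv"
    pd.DataFrame(grid, index=[f"row{i}" for i in range(1, 5)],
                 columns=[f"col{j}" for j in range(1, 5)]).to_csv(paths["importance_matrix"])

    acc = accuracy(cm)
    lines = [
        f"instances: {int(cm.to_numpy().sum())}",
        f"accuracy: {acc:.6f} (presented: {round_half_away(acc):.2f})",
        f"mean AUC: {aucs.get('mean', float('nan')):.6f}",
        "top features: " + ", ".join(
            f"{r.feature}={r.importance:.3f}" for r in ranking.head(4).itertuples()
        ),
    ]
    paths["summary"] = out / "summary.log"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
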