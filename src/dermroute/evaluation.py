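"""Evaluation: balanced accuracy, one-vs-rest AUROC, ROC curves,
multi-run aggregation, and the (alpha1, alpha2) threshold grid search.

Balanced accuracy (BACC) is the unweighted mean of per-class
sensitivities — the right summary under the heavy nevus/melanoma class
imbalance, where plain accuracy would reward always predicting nevus.
AUROC is computed one-vs-rest per class with midrank tie handling
(Mann-Whitney), via scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .routing import (
    CLASSES,
    ClassifierBundle,
    ConfidenceThresholds,
    predict,
)

__all__ = [
    "ConfusionMatrix",
    "GridSearchResult",
    "bacc",
    "auroc_ovr",
    "roc_curve",
    "grid_search_thresholds",
    "aggregate_runs",
    "DEFAULT_GRID",
]

#: Default (alpha1, alpha2) grid: {0.1, 0.2, 0.3} x {0.3, 0.4, 0.5}
#: restricted to alpha1 < alpha2.
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (a1, a2)
    for a1 in (0.1, 0.2, 0.3)
    for a2 in (0.3, 0.4, 0.5)
    if a1 < a2
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted, order (B, M, N)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape[0] != arr.shape[1] or np.any(arr < 0):
            raise ValueError("confusion matrix must be square and non-negative")
        object.__setattr__(self, "counts", arr.astype(int))

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str],
                    labels: Sequence[str] = CLASSES) -> "ConfusionMatrix":
        return cls(_sk_confusion(list(y_true), list(y_pred), labels=list(labels)))


def bacc(cm: ConfusionMatrix) -> float:
    """Balanced accuracy: mean over classes of per-class sensitivity."""
    counts = cm.counts
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class needs at least one sample")
    sens = np.diag(counts) / row_sums
    return float(sens.mean())


def auroc_ovr(
    scores: np.ndarray, labels: Sequence[str], classes: Sequence[str] = CLASSES
) -> tuple[dict[str, float], float]:
    """One-vs-rest AUROC per class plus the macro average.

    ``scores`` is (n_samples, n_classes) in ``classes`` order; ties are
    handled by midranks (rank-based Mann-Whitney statistic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    per_class = {}
    for j, c in enumerate(classes):
        y = (labels == c).astype(int)
        if y.min() == y.max():
            raise ValueError(f"class {c!r}: need both positives and negatives")
        per_class[c] = float(roc_auc_score(y, scores[:, j]))
    return per_class, float(np.mean(list(per_class.values())))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC staircase from (0,0) to (1,1) as an array of (FPR, TPR) rows.

    The trapezoidal area under the returned curve equals the midrank
    AUROC for the same inputs.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("need both positive and negative labels")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class GridSearchResult:
    grid: tuple  # of (alpha1, alpha2, objective value)
    best: tuple[float, float]
    objective_name: str


def _framework_outputs(bundle, xs, thresholds, priority=None):
    from .routing import TIE_PRIORITY

    traces = [
        predict(x, bundle, thresholds, priority or TIE_PRIORITY) for x in xs
    ]
    preds = [t.final_class for t in traces]
    probs = np.vstack([t.final_probs.as_array() for t in traces])
    return preds, probs


def grid_search_thresholds(
    bundle: ClassifierBundle,
    xs: Sequence,
    labels: Sequence[str],
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    objective: str = "BACC",
) -> GridSearchResult:
    """Tune (alpha1, alpha2) on a validation set.

    Runs the full routing framework at every grid point and scores it by
    the chosen objective: ``"BACC"`` (balanced accuracy of the final
    decisions) or ``"MEL-AUROC"`` (one-vs-rest AUROC of the final
    melanoma probability).  Ties favour smaller alpha1, then alpha2.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if objective not in ("BACC", "MEL-AUROC"):
        raise ValueError(f"unknown objective {objective!r}")
    labels = np.asarray(labels)
    rows = []
    for a1, a2 in grid:
        t = ConfidenceThresholds(a1, a2)  # validates a1 <= a2
        preds, probs = _framework_outputs(bundle, xs, t)
        if objective == "BACC":
            val = bacc(ConfusionMatrix.from_labels(labels, preds))
        else:
            y = (labels == "M").astype(int)
            val = float(roc_auc_score(y, probs[:, CLASSES.index("M")]))
        rows.append((float(a1), float(a2), val))
    best = min(rows, key=lambda r: (-r[2], r[0], r[1]))
    return GridSearchResult(tuple(rows), (best[0], best[1]), objective)


def aggregate_runs(runs: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Mean and sample standard deviation per metric over repeated runs."""
    if len(runs) < 2:
        raise ValueError("need at least two runs to aggregate")
    df = pd.DataFrame(list(runs))
    out = pd.DataFrame({"mean": df.mean(), "std": df.std(ddof=1)})
    out["report"] = [
        f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["std"])
    ]
    return out
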