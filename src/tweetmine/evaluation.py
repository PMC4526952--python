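"""Cross-validated evaluation: stratified folds, accuracy, per-class
ROC/AUC and precision-recall break-even.

Per-class metrics are one-vs-rest on the class's softmax score; a prediction
is positive when the score meets the threshold (closed lower bound).  AUC is
computed exactly as the Mann-Whitney statistic, P(score_pos > score_neg) +
0.5 P(equal), which equals the trapezoidal area under the threshold-swept ROC
curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "stratified_folds",
    "CVReport",
    "cross_validate",
    "multiclass_accuracy",
    "topk_accuracy",
    "roc_points",
    "auc",
    "break_even",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of items into k folds, per-class balanced within +/- 1."""

    fold_of: tuple[int, ...]
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) != fold)


def stratified_folds(labels: Sequence, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified assignment: within each class, items are shuffled (seeded)
    and dealt round-robin to folds 0..k-1.

    A class with fewer than k members therefore appears in exactly that many
    folds; per-class fold counts differ by at most 1.
    """
    labels = list(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in sorted(set(map(str, labels))):
        idx = np.array([i for i, y in enumerate(labels) if str(y) == cls])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = pos % k
    return FoldAssignment(tuple(int(f) for f in fold_of), k, seed)


def multiclass_accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Exact-match fraction."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if not len(truth):
        raise ValueError("empty input")
    return sum(p == t for p, t in zip(predicted, truth)) / len(truth)


def topk_accuracy(scores: np.ndarray, truth: Sequence[int], k: int = 2) -> float:
    """Fraction of items whose true class index is among the k top-scoring
    classes; score ties break by category order (lower index wins)."""
    scores = np.asarray(scores, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > scores.shape[1]:
        raise ValueError("k exceeds the number of categories")
    truth = np.asarray(truth, dtype=int)
    # stable sort on (-score, index): mergesort keeps lower index first on ties
    order = np.argsort(-scores, axis=1, kind="stable")
    hits = (order[:, :k] == truth[:, None]).any(axis=1)
    return float(hits.mean())


def _check_binary(truth: np.ndarray) -> None:
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")


def roc_points(scores: Sequence[float], truth: Sequence[bool]) -> pd.DataFrame:
    """Threshold sweep: (threshold, recall, precision, fall_out) rows.

    Thresholds are the distinct score values in descending order (prediction
    positive iff score >= threshold) plus an all-negative endpoint above the
    maximum; precision is undefined (omitted, NaN) at zero predicted
    positives.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    _check_binary(t)
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    rows = []
    for thr in thresholds:
        pred = s >= thr
        tp = int((pred & t).sum())
        fp = int((pred & ~t).sum())
        recall = tp / n_pos
        fall_out = fp / n_neg
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        rows.append((thr, recall, precision, fall_out))
    return pd.DataFrame(rows, columns=["threshold", "recall", "precision", "fall_out"])


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Exact Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    _check_binary(t)
    ranks = rankdata(s)  # midranks handle ties exactly
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def trapezoid_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """AUC by trapezoidal integration of the swept ROC curve (cross-check
    route for :func:`auc`)."""
    pts = roc_points(scores, truth)
    # sweep order already runs (0,0) -> (1,1) as the threshold decreases
    x = pts["fall_out"].to_numpy()
    y = pts["recall"].to_numpy()
    # ensure the (1,1) endpoint closes the curve
    if x[-1] < 1.0 or y[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    return float(np.trapezoid(y, x))


def break_even(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Precision-recall break-even point, as a percentage.

    Sweeps thresholds descending; returns the common precision=recall value
    where the two curves cross, linearly interpolating between the adjacent
    sweep points when the crossing falls between thresholds, else the value
    at the point minimizing |precision - recall|.
    """
    t = np.asarray(truth, dtype=bool)
    if not t.any():
        raise ValueError("break_even needs at least one positive")
    pts = roc_points(scores, t).dropna(subset=["precision"])
    prec = pts["precision"].to_numpy()
    rec = pts["recall"].to_numpy()
    if not len(prec):
        raise ValueError("no thresholds with predicted positives")
    diff = prec - rec
    # exact crossing at a sweep point
    exact = np.flatnonzero(np.isclose(diff, 0.0))
    if exact.size:
        return float(prec[exact[0]] * 100.0)
    sign_change = np.flatnonzero(diff[:-1] * diff[1:] < 0)
    if sign_change.size:
        i = int(sign_change[0])
        # linear interpolation in sweep order: find alpha with d=0
        alpha = diff[i] / (diff[i] - diff[i + 1])
        value = prec[i] + alpha * (prec[i + 1] - prec[i])
        return float(value * 100.0)
    i = int(np.argmin(np.abs(diff)))
    return float(prec[i] * 100.0)


class _Estimator(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Estimator": ...
    def predict_scores(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class CVReport:
    """Pooled cross-validation results."""

    folds: FoldAssignment
    categories: tuple[str, ...]
    pooled_scores: np.ndarray  # (n_items, n_categories), rows in item order
    predicted: tuple[str, ...]
    truth: tuple[str, ...]
    fold_accuracy: tuple[float, ...]
    accuracy: float
    top2_accuracy: float
    per_class: pd.DataFrame  # columns: category, auc, break_even
    confusion: pd.DataFrame  # rows true, columns predicted


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    factory: Callable[[], _Estimator],
    folds: FoldAssignment,
    categories: Sequence[str],
) -> CVReport:
    """Train a fresh estimator per fold and pool held-out predictions.

    ``factory`` returns an unfitted estimator exposing ``fit(X, y)`` (y as
    integer indices into ``categories``) and ``predict_scores(X)``.
    Per-class AUC/break-even are computed one-vs-rest on the pooled scores;
    a class absent from the pooled truth is skipped with a warning.
    """
    y = list(map(str, y))
    categories = tuple(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    y_idx = np.array([cat_index[c] for c in y])
    n = X.shape[0]
    if len(y) != n:
        raise ValueError("X rows and y length differ")
    pooled = np.zeros((n, len(categories)))
    fold_acc = []
    for fold in range(folds.k):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        missing = set(range(len(categories))) - set(y_idx[tr])
        if missing:
            logger.warning(
                "fold %d: no training instances of %s",
                fold,
                [categories[i] for i in sorted(missing)],
            )
        est = factory().fit(X[tr], y_idx[tr])
        pooled[te] = est.predict_scores(X[te])
        pred_te = np.argmax(pooled[te], axis=1)
        fold_acc.append(float((pred_te == y_idx[te]).mean()))
    predicted = tuple(categories[i] for i in np.argmax(pooled, axis=1))
    accuracy = multiclass_accuracy(predicted, y)
    top2 = topk_accuracy(pooled, y_idx, k=min(2, len(categories)))
    rows = []
    for j, cat in enumerate(categories):
        member = y_idx == j
        if member.all() or not member.any():
            logger.warning("per-class metrics skipped for %r (single-class truth)", cat)
            rows.append((cat, np.nan, np.nan))
            continue
        rows.append(
            (cat, auc(pooled[:, j], member), break_even(pooled[:, j], member))
        )
    per_class = pd.DataFrame(rows, columns=["category", "auc", "break_even"])
    confusion = pd.crosstab(
        pd.Categorical(y, categories=categories),
        pd.Categorical(predicted, categories=categories),
        dropna=False,
    )
    confusion.index = pd.Index(categories, name="true")
    confusion.columns = pd.Index(categories, name="predicted")
    return CVReport(
        folds=folds,
        categories=categories,
        pooled_scores=pooled,
        predicted=predicted,
        truth=tuple(y),
        fold_accuracy=tuple(fold_acc),
        accuracy=accuracy,
        top2_accuracy=top2,
        per_class=per_class,
        confusion=confusion,
    )
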