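"""Evaluation metrics for binary semantic-characteristic grading.

Implements accuracy, recall (sensitivity), the rank-statistic AUC
(equivalent to the Mann-Whitney U statistic under mean-rank tie
handling) and the Dice similarity coefficient, plus a grouped,
stratified fivefold cross-validation driver that keeps all patches and
slices of one nodule inside a single fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

#: Sentinel returned where a metric's denominator vanishes (e.g. recall
#: with no positive truths, AUC with a single class present).
UNDEFINED = float("nan")


def _is_undefined(x: float) -> bool:
    return np.isnan(x)


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation split."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    rec: float
    auc: float
    dsc: float
    sc: str = ""
    fold: int = -1
    split: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(labels: Sequence[int], predictions: Sequence[int]) -> tuple[int, int, int, int]:
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return tp, fp, tn, fn


def accuracy_recall(labels: Sequence[int], predictions: Sequence[int]) -> tuple[float, float]:
    """ACC = (TP+TN)/n and REC = TP/(TP+FN).

    Recall is the undefined marker (NaN) when there are no positive
    ground-truth samples.
    """
    tp, fp, tn, fn = confusion_counts(labels, predictions)
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty input")
    acc = (tp + tn) / n
    rec = UNDEFINED if tp + fn == 0 else tp / (tp + fn)
    return acc, rec


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC.

    AUC = (sum of positive-sample ranks - M(M+1)/2) / (M*N) with ranks
    ascending by score and tied scores receiving the mean of their rank
    span, which makes the statistic equal the fraction of
    positive-negative pairs correctly ordered (ties counting 1/2).
    Returns the undefined marker when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("length mismatch between scores and labels")
    m = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if m == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(s, method="average")
    return (float(np.sum(ranks[y == 1])) - m * (m + 1) / 2.0) / (m * n_neg)


def dsc(a: Sequence[int], b: Sequence[int]) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Accepts binary indicator vectors (same length) or explicit sets.
    Defined as 1.0 when both sets are empty.
    """
    if isinstance(a, (set, frozenset)) or isinstance(b, (set, frozenset)):
        sa, sb = set(a), set(b)
        na, nb, ni = len(sa), len(sb), len(sa & sb)
    else:
        va = np.asarray(a).astype(bool).ravel()
        vb = np.asarray(b).astype(bool).ravel()
        if va.shape != vb.shape:
            raise ValueError("indicator vectors must have equal length")
        na, nb, ni = int(va.sum()), int(vb.sum()), int((va & vb).sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * ni / (na + nb)


def evaluate_binary(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    sc: str = "",
    fold: int = -1,
    split: str = "",
) -> EvalReport:
    """Threshold scores and compute the full metric set."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp, fp, tn, fn = confusion_counts(y, pred)
    acc, rec = accuracy_recall(y, pred)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, rec=rec,
        auc=auc_rank(s, y),
        dsc=dsc(y == 1, pred == 1),
        sc=sc, fold=fold, split=split,
    )


def fold_assignment(labels: Sequence[int], n_splits: int, seed: int) -> np.ndarray:
    """Seeded stratified fold labels, one per sample (nodule).

    Per-class fold sizes differ by at most one. The grouping unit is
    the nodule: callers pass one label per nodule, and every patch or
    slice triplet derived from that nodule inherits its fold.
    """
    y = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = k
    return folds


def fivefold_cv(
    labels: Sequence[int],
    train_eval_fn: Callable[[np.ndarray, np.ndarray, int], tuple[np.ndarray, np.ndarray]],
    seed: int,
    n_splits: int = 5,
    sc: str = "",
) -> dict:
    """Stratified fivefold cross-validation over nodules.

    ``train_eval_fn(train_idx, test_idx, fold_seed)`` must train a model
    on the training nodules and return ``(train_scores, test_scores)``
    — predicted probabilities for the two index sets. Returns per-fold
    train/test :class:`EvalReport` lists and their mean accuracies.
    """
    y = np.asarray(labels).astype(int)
    if len(y) < 10:
        raise ValueError("need at least 10 samples for fivefold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    folds = fold_assignment(y, n_splits, seed)
    # one re-stratification attempt if some training split lost a class
    for attempt in range(2):
        ok = all(
            len(np.unique(y[folds != k])) == 2 for k in range(n_splits)
        )
        if ok:
            break
        if attempt == 1:
            raise ValueError("a class is absent from a fold's training split")
        folds = fold_assignment(y, n_splits, seed + 1)

    train_reports: list[EvalReport] = []
    test_reports: list[EvalReport] = []
    for k in range(n_splits):
        train_idx = np.flatnonzero(folds != k)
        test_idx = np.flatnonzero(folds == k)
        s_train, s_test = train_eval_fn(train_idx, test_idx, seed * n_splits + k)
        train_reports.append(evaluate_binary(y[train_idx], s_train, sc=sc, fold=k, split="train"))
        test_reports.append(evaluate_binary(y[test_idx], s_test, sc=sc, fold=k, split="test"))
    return {
        "sc": sc,
        "folds": folds,
        "train": train_reports,
        "test": test_reports,
        "mean_train_acc": float(np.mean([r.acc for r in train_reports])),
        "mean_test_acc": float(np.mean([r.acc for r in test_reports])),
    }


def average_accuracy(reports: dict[str, float]) -> float:
    """Ave: arithmetic mean of per-SC accuracies."""
    return float(np.mean(list(reports.values())))
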