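"""Train/test splitting, (C, sigma) grid search and the four assessment criteria.

Per class c (one-vs-rest) the confusion counts are nTP, nFN, nFP, nTN and
the criteria are

    sensitivity  gTP = nTP / (nTP + nFN)
    specificity  gTN = nTN / (nTN + nFP)
    precision    gPP = nTP / (nTP + nFP)
    F1           g   = 2 nTP / (2 nTP + nFP + nFN)

plus the overall prediction accuracy Pa = n_correct / n_total.  F1 equals
the harmonic mean of precision and sensitivity wherever both are defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

from .ga import evaluate_fitness
from .svm import SVMParams

__all__ = [
    "split_train_test",
    "default_grid",
    "grid_search_params",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "harmonic_f1",
]


def split_train_test(
    labels,
    train_fraction: float = 0.8,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split; returns (train_indices, test_indices).

    The training count is the round-up of ``train_fraction * N`` (an 80/20
    split of 332 samples gives 266/66).  Stratified splitting keeps class
    proportions and requires every class to have at least 2 samples.
    """
    y = np.asarray(labels)
    n = y.size
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = math.ceil(round(train_fraction * n, 9))
    n_train = min(n_train, n - 1)
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError(
                "stratified split needs >= 2 samples per class "
                f"(smallest class has {counts.min()})"
            )
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=n_train, test_size=n - n_train, random_state=seed
        )
    else:
        splitter = ShuffleSplit(
            n_splits=1, train_size=n_train, test_size=n - n_train, random_state=seed
        )
    train_idx, test_idx = next(splitter.split(np.zeros((n, 1)), y))
    return np.sort(train_idx), np.sort(test_idx)


def default_grid() -> np.ndarray:
    """Half-power-of-two grid 2^(i/2), i = -4..4 (~0.25 ... 4.0)."""
    return 2.0 ** (np.arange(-4, 5) / 2.0)


def grid_search_params(
    X,
    y,
    Cs=None,
    sigmas=None,
    folds: int = 5,
    seed: int = 0,
    split_policy: str = "centroid",
) -> tuple[SVMParams, pd.DataFrame]:
    """Exhaustive (C, sigma) search by stratified k-fold CV accuracy.

    Returns the maximising pair (ties broken by smaller C, then smaller
    sigma) and the full accuracy table.
    """
    Cs = default_grid() if Cs is None else np.asarray(Cs, dtype=float)
    sigmas = default_grid() if sigmas is None else np.asarray(sigmas, dtype=float)
    if Cs.size == 0 or sigmas.size == 0:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X, dtype=float)
    full_mask = np.ones(X.shape[1], dtype=bool)
    rows = []
    best: tuple[float, float, float] | None = None  # (acc, C, sigma)
    for c in np.sort(Cs):
        for s in np.sort(sigmas):
            acc = evaluate_fitness(
                full_mask, X, y, SVMParams(c, s), cv_folds=folds, seed=seed,
                split_policy=split_policy,
            )
            rows.append({"C": c, "sigma": s, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, c, s)
    table = pd.DataFrame(rows)
    assert best is not None
    return SVMParams(C=best[1], sigma=best[2]), table


@dataclass
class ConfusionMatrix:
    """One-vs-rest confusion counts for every class."""

    classes: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    n_correct: int
    n_total: int

    def __post_init__(self) -> None:
        for arr in (self.tp, self.fn, self.fp, self.tn):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("confusion counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.classes, "nTP": self.tp, "nFN": self.fn,
             "nFP": self.fp, "nTN": self.tn}
        )


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Per-class one-vs-rest confusion counts plus the overall tally."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    classes = np.unique(np.concatenate([y_true, y_pred])) if labels is None \
        else np.asarray(labels)
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=classes)
    return ConfusionMatrix(
        classes=classes,
        tp=mcm[:, 1, 1],
        fn=mcm[:, 1, 0],
        fp=mcm[:, 0, 1],
        tn=mcm[:, 0, 0],
        n_correct=int(np.sum(y_true == y_pred)),
        n_total=int(y_true.size),
    )


@dataclass
class MetricsReport:
    """Per-class sensitivity/specificity/precision/F1 and overall accuracy."""

    classes: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
                "f1": self.f1,
            }
        )


def _safe_ratio(num, den, name) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(f"{name} undefined for {int((~ok).sum())} class(es)",
                      stacklevel=3)
    return out


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four per-class criteria plus overall prediction accuracy."""
    if cm.n_total <= 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        classes=cm.classes,
        sensitivity=_safe_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_safe_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        precision=_safe_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        f1=_safe_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1"),
        accuracy=cm.n_correct / cm.n_total,
    )


def harmonic_f1(sensitivity: float, precision: float) -> float:
    """F1 as the harmonic mean of sensitivity and precision."""
    if sensitivity + precision == 0:
        return float("nan")
    return 2.0 * sensitivity * precision / (sensitivity + precision)
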