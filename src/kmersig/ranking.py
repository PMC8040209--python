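"""Univariate feature ranking by cross-validated F1 of a Bayes classifier.

Each feature (on the log1p-normalized scale) is scored independently: a
one-dimensional Gaussian naive Bayes classifier (class-conditional normal
with class priors estimated from the training fold) is fit per fold of a
stratified 5-fold split and evaluated by the F1 score of the positive
class on the held-out fold; the feature's score is the mean over folds.
Folds where F1 is undefined contribute 0 (the worst score), and features
that are constant across the cohort score 0 outright.  The top ``top_n``
features (default 500) are retained for signature selection.

One shared fold split is used for every feature, so scores are comparable
across features and the whole matrix can be scored in a few vectorized
passes rather than per-feature model fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-9


@dataclass(frozen=True)
class RankedFeature:
    feature: str
    mean_f1: float
    rank: int


def _as_binary_labels(labels, samples) -> np.ndarray:
    """Accept CohortLabels, Series or array; return 0/1 aligned to samples."""
    if hasattr(labels, "binary"):
        y = labels.binary(samples)
        missing = [s for s in samples if s not in y.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        return y.reindex(samples).to_numpy()
    if isinstance(labels, pd.Series):
        return labels.reindex(samples).astype(int).to_numpy()
    return np.asarray(labels, dtype=int)


def _fold_split(y: np.ndarray, folds: int, seed: int):
    """Shared stratified folds; shrink fold count if a class is too small."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to rank features")
    min_class = int(counts.min())
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds from {folds}"
        )
        folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def _f1_per_fold(X: np.ndarray, y: np.ndarray, train, test) -> np.ndarray:
    """Positive-class F1 of the 1-D Gaussian Bayes rule, per feature."""
    Xtr, Xte = X[:, train], X[:, test]
    ytr, yte = y[train], y[test]
    n_tr = ytr.size
    scores = np.zeros(X.shape[0])
    ll = {}
    for c in (0, 1):
        cols = Xtr[:, ytr == c]
        if cols.shape[1] == 0:
            return scores  # degenerate fold: no model, F1 = 0
        mu = cols.mean(axis=1)
        var = cols.var(axis=1) + VARIANCE_FLOOR
        prior = cols.shape[1] / n_tr
        ll[c] = (
            -0.5 * np.log(2 * np.pi * var)[:, None]
            - (Xte - mu[:, None]) ** 2 / (2 * var[:, None])
            + np.log(prior)
        )
    pred = ll[1] > ll[0]  # ties resolve to the negative class
    pos = yte == 1
    tp = (pred & pos).sum(axis=1)
    fp = (pred & ~pos).sum(axis=1)
    fn = (~pred & pos).sum(axis=1)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return f1


def _mean_f1(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    splits = _fold_split(y, folds, seed)
    total = np.zeros(X.shape[0])
    for train, test in splits:
        total += _f1_per_fold(X, y, train, test)
    mean = total / len(splits)
    mean[X.std(axis=1) == 0] = 0.0  # constant features carry no signal
    return mean


def univariate_f1(values, labels, folds: int = 5, seed: int = 0) -> float:
    """Mean cross-validated positive-class F1 of one feature."""
    x = np.asarray(values, dtype=float).reshape(1, -1)
    y = np.asarray(labels, dtype=int)
    if x.shape[1] != y.size:
        raise ValueError("values and labels must have equal length")
    return float(_mean_f1(x, y, folds, seed)[0])


def rank_features(
    values: pd.DataFrame,
    labels,
    top_n: int = 500,
    folds: int = 5,
    seed: int = 0,
) -> list[RankedFeature]:
    """Score every feature by cross-validated F1 and return the top ``top_n``.

    ``values`` is a features x samples DataFrame on the log1p-normalized
    scale; ``labels`` a CohortLabels, Series or 0/1 array over its columns.
    Ties are broken by feature id so the ranking is fully deterministic.
    """
    samples = list(values.columns)
    y = _as_binary_labels(labels, samples)
    X = values.to_numpy(dtype=float)
    mean_f1 = _mean_f1(X, y, folds, seed)

    order = sorted(range(len(values.index)), key=lambda i: (-mean_f1[i], values.index[i]))
    if top_n > len(order):
        warnings.warn(f"top_n={top_n} exceeds feature count {len(order)}; returning all")
    kept = order[:top_n]
    return [
        RankedFeature(feature=str(values.index[i]), mean_f1=float(mean_f1[i]), rank=r + 1)
        for r, i in enumerate(kept)
    ]


def ranking_frame(ranked: list[RankedFeature]) -> pd.DataFrame:
    """Ranking as a DataFrame (feature, mean_f1, rank)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in ranked],
            "mean_f1": [r.mean_f1 for r in ranked],
            "rank": [r.rank for r in ranked],
        }
    ).set_index("feature")
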