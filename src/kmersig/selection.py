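"""Sparse signature selection, final logistic fit, and CV evaluation.

From the top-ranked features, a sparse signature is chosen by *stability
selection*: the cohort is subsampled many times (stratified halves, without
replacement), an L1-penalized logistic regression is fit on each subsample
with its penalty chosen by internal cross-validation (one-standard-error
rule, favouring the sparser end of the path), and only features whose
selection frequency exceeds a threshold (default: > 0.5 over 2000
resamples) are retained.  A final logistic regression on the whole
discovery cohort provides the signature's coefficients; performance is
estimated by repeated stratified 10-fold cross-validation (ROC AUC and
precision-recall AUC), with optional over-/down-sampling of the training
folds only, so no information leaks across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, log_loss, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import l1_min_c

from kmersig.io import read_json, write_fasta, write_json

logger = logging.getLogger(__name__)


class EmptySignatureError(RuntimeError):
    """Raised when stability selection retains no feature at all."""


# ---------------------------------------------------------------------------
# signature container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureFeature:
    id: str
    coefficient: float
    sequence: str | None = None


@dataclass
class Signature:
    """A sparse logistic model over contig or gene features.

    Scores are computed on log(normalized + 1) values:
    p = sigmoid(intercept + sum_f coef_f * x_f).
    """

    task: str
    features: list[SignatureFeature]
    intercept: float
    base_constant: float
    transform: str = "log1p of normalized counts"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.features:
            if not np.isfinite(f.coefficient):
                raise ValueError(f"non-finite coefficient for feature {f.id}")

    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]

    def coefficients(self) -> pd.Series:
        return pd.Series(
            {f.id: f.coefficient for f in self.features}, name="coefficient"
        )

    def decision_values(self, values: pd.DataFrame, missing: str = "error") -> pd.Series:
        """Linear scores for samples (columns of ``values``).

        ``values`` must be on the signature's transform scale.  Features
        absent from ``values`` raise unless ``missing='zero'``, in which
        case their coefficients are zeroed (the cross-cohort convention).
        """
        score = np.full(len(values.columns), float(self.intercept))
        for f in self.features:
            if f.id in values.index:
                score = score + f.coefficient * values.loc[f.id].to_numpy(dtype=float)
            elif missing == "zero":
                continue
            else:
                raise KeyError(f"feature {f.id} missing from the value matrix")
        return pd.Series(score, index=values.columns, name="score")

    def predict_proba(self, values: pd.DataFrame, missing: str = "error") -> pd.Series:
        return pd.Series(
            expit(self.decision_values(values, missing=missing)),
            index=values.columns,
            name="probability",
        )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "features": [asdict(f) for f in self.features],
            "intercept": self.intercept,
            "base_constant": self.base_constant,
            "transform": self.transform,
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            task=d["task"],
            features=[SignatureFeature(**f) for f in d["features"]],
            intercept=d["intercept"],
            base_constant=d["base_constant"],
            transform=d.get("transform", "log1p of normalized counts"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "Signature":
        return cls.from_dict(read_json(path))

    def save_fasta(self, path) -> None:
        entries = [(f.id, f.sequence) for f in self.features if f.sequence]
        write_fasta(path, entries)


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    frequencies: pd.Series
    n_resamples: int
    threshold: float

    @property
    def selected(self) -> list[str]:
        """Features with frequency strictly above the threshold."""
        hits = self.frequencies[self.frequencies > self.threshold]
        return list(hits.sort_values(ascending=False, kind="stable").index)


def _stratified_half(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-stratified half subsample, without replacement."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        take = max(1, members.size // 2)
        idx.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def _penalty_grid(X: np.ndarray, y: np.ndarray, n_penalties: int) -> np.ndarray:
    """C grid from just above the all-zero threshold to a weak penalty."""
    c_min = l1_min_c(X, y, loss="log")
    return c_min * np.logspace(0.05, 2, n_penalties)


def _lasso_fit(X, y, C):
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=500, tol=1e-4, random_state=0
    )
    model.fit(X, y)
    return model


def _choose_penalty(
    X, y, Cs, folds: int, rng: np.random.Generator, rule: str = "min"
) -> float:
    """Internal CV over the C grid.

    ``rule="min"`` (default) picks the loss-minimizing C, the analogue of
    glmnet's lambda.min; ``rule="1se"`` picks the sparsest C within one
    standard error of the best.  The min rule keeps per-resample models
    dense enough that groups of correlated informative features do not
    split their selection frequency below the stability threshold.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = np.zeros((len(Cs), folds))
    for f, (train, test) in enumerate(skf.split(X, y)):
        if np.unique(y[test]).size < 2 or np.unique(y[train]).size < 2:
            losses[:, f] = np.nan
            continue
        for i, C in enumerate(Cs):
            model = _lasso_fit(X[train], y[train], C)
            p = model.predict_proba(X[test])[:, 1]
            losses[i, f] = log_loss(y[test], p, labels=[0, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(losses, axis=1)
        se = np.nanstd(losses, axis=1, ddof=1) / np.sqrt(
            np.sum(~np.isnan(losses), axis=1).clip(min=1)
        )
    if np.all(np.isnan(mean)):
        return float(Cs[0])
    best = int(np.nanargmin(mean))
    if rule == "min":
        return float(Cs[best])
    cutoff = mean[best] + se[best]
    for i in range(len(Cs)):  # Cs ascend: smallest C = strongest penalty
        if mean[i] <= cutoff:
            return float(Cs[i])
    return float(Cs[best])


def stability_select(
    X: pd.DataFrame,
    y,
    n_resamples: int = 2000,
    threshold: float = 0.5,
    seed: int = 0,
    internal_folds: int = 3,
    n_penalties: int = 5,
    penalty_rule: str = "min",
    max_redraws: int = 10,
) -> StabilityResult:
    """Per-feature selection frequencies over lasso fits on half subsamples.

    ``X`` is samples x features on the modelling scale, ``y`` binary.
    Features whose frequency exceeds ``threshold`` (strictly) form the
    selected set, exposed by :attr:`StabilityResult.selected`.  Each
    resample's L1 penalty comes from internal cross-validation under
    ``penalty_rule`` ("min" or "1se", see :func:`_choose_penalty`).
    """
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=int)
    if np.unique(yv).size < 2:
        raise ValueError("both classes required for stability selection")

    hits = np.zeros(len(feature_names))
    streams = np.random.SeedSequence(seed).spawn(n_resamples)
    for r in range(n_resamples):
        rng = np.random.default_rng(streams[r])
        sub = None
        for _ in range(max_redraws):
            cand = _stratified_half(yv, rng)
            if np.unique(yv[cand]).size == 2:
                sub = cand
                break
        if sub is None:
            warnings.warn(f"resample {r}: could not keep both classes, recorded empty")
            continue
        Xs, ys = Xv[sub], yv[sub]
        # standardize within the resample so the L1 penalty is scale-fair
        # (glmnet's default behaviour)
        sd = Xs.std(axis=0)
        Xs = (Xs - Xs.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                C = _choose_penalty(Xs, ys, _penalty_grid(Xs, ys, n_penalties),
                                    internal_folds, rng, rule=penalty_rule)
                model = _lasso_fit(Xs, ys, C)
        except (ConvergenceWarning, ValueError) as exc:
            warnings.warn(f"resample {r}: lasso failed ({exc}), recorded empty")
            continue
        hits += (np.abs(model.coef_[0]) > 1e-8).astype(float)

    freq = pd.Series(hits / n_resamples, index=feature_names, name="frequency")
    return StabilityResult(frequencies=freq, n_resamples=n_resamples, threshold=threshold)


# ---------------------------------------------------------------------------
# final model and evaluation
# ---------------------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unpenalized logistic fit; tiny-ridge fallback under separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            model.fit(X, y)
            return model
    except ConvergenceWarning:
        logger.info("unpenalized logistic did not converge (separation?); "
                    "refitting with a tiny L2 penalty")
        model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        return model


def fit_final_model(
    X: pd.DataFrame,
    y,
    task: str,
    base_constant: float,
    sequences: dict[str, str] | None = None,
    metadata: dict | None = None,
) -> Signature:
    """Fit the signature's logistic regression on the whole discovery set.

    ``X`` is samples x selected-features; raises
    :class:`EmptySignatureError` when no feature was selected, rather than
    returning a silent constant model.
    """
    if X.shape[1] == 0:
        raise EmptySignatureError("stability selection retained no feature")
    yv = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    if X.columns.duplicated().any() or (
        Xv.shape[1] > 1 and np.linalg.matrix_rank(Xv - Xv.mean(0)) < Xv.shape[1]
    ):
        warnings.warn("selected feature matrix is collinear; coefficients are unstable")
    model = _fit_logistic(Xv, yv)
    sequences = sequences or {}
    features = [
        SignatureFeature(
            id=str(name),
            coefficient=float(coef),
            sequence=sequences.get(str(name)),
        )
        for name, coef in zip(X.columns, model.coef_[0])
    ]
    return Signature(
        task=task,
        features=features,
        intercept=float(model.intercept_[0]),
        base_constant=float(base_constant),
        metadata=metadata or {},
    )


def _resample_training(Xtr, ytr, sampling: str, rng: np.random.Generator):
    """Up-/down-sample the training fold to balance classes."""
    if sampling == "none":
        return Xtr, ytr
    pos = np.flatnonzero(ytr == 1)
    neg = np.flatnonzero(ytr == 0)
    small, large = (pos, neg) if pos.size < neg.size else (neg, pos)
    if sampling == "up":
        extra = rng.choice(small, size=large.size - small.size, replace=True)
        idx = np.concatenate([pos, neg, extra])
    elif sampling == "down":
        kept = rng.choice(large, size=small.size, replace=False)
        idx = np.concatenate([small, kept])
    else:
        raise ValueError(f"sampling must be none/up/down, got {sampling!r}")
    idx = np.sort(idx)
    return Xtr[idx], ytr[idx]


def evaluate_cv(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    repeats: int = 20,
    sampling: str = "none",
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold ROC AUC and PR AUC of the logistic model.

    Sampling (if any) is applied to training folds only.  Returns
    ``{"roc_auc": ..., "pr_auc": ..., "n_folds_used": ...}`` with means
    over all usable held-out folds.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y, dtype=int)
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2 or counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} members for {folds}-fold CV")
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rng = np.random.default_rng(seed)
    rocs, prs = [], []
    for train, test in rskf.split(Xv, yv):
        if np.unique(yv[test]).size < 2:
            warnings.warn("held-out fold lacks a class; skipped")
            continue
        Xtr, ytr = _resample_training(Xv[train], yv[train], sampling, rng)
        model = _fit_logistic(Xtr, ytr)
        p = model.predict_proba(Xv[test])[:, 1]
        rocs.append(roc_auc_score(yv[test], p))
        prs.append(average_precision_score(yv[test], p))
    return {
        "roc_auc": float(np.mean(rocs)),
        "pr_auc": float(np.mean(prs)),
        "n_folds_used": len(rocs),
    }
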