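"""Predictive evaluation of the functionality scores.

The protocol deliberately mirrors how a small biomarker cohort is usually
stress-tested: a gradient-boosted tree classifier restricted to a *single*
boosting round (one shallow tree, so the model cannot overfit three features
on ~29 patients), 3-fold stratified cross-validation with the out-of-fold
risk scores pooled into one test AUC, and the whole CV repeated over
bootstrap-resampled cohorts of sizes 15..29 (100 resamples per size) to map
how predictive power degrades with cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import IcarError

__all__ = [
    "FeatureMatrix",
    "PredictiveEvalResult",
    "SingleRoundTreeModel",
    "train_single_round_model",
    "roc_auc",
    "cv_auc",
    "cohort_sampling_curve",
    "curve_to_frame",
]

FEATURE_NAMES = ("pd1_score", "pdl1_score", "pdl2_score")
PROTOCOL_SIZES = tuple(range(15, 30))

_XGB_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class FeatureMatrix:
    """Patients x three functionality scores, with responder labels."""

    X: np.ndarray  # (n, 3) float
    y: np.ndarray  # (n,) bool
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=bool)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise IcarError("shape_mismatch", "X must be (n, p) with one label per row")
        if np.isnan(X).any():
            raise IcarError("missing_features", "feature matrix contains missing values")

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @classmethod
    def from_cohort(cls, cohort) -> "FeatureMatrix":
        """Build from PatientRecords, dropping patients missing any score."""
        rows, labels = [], []
        for p in cohort:
            scores = [p.score(name.removesuffix("_score")) for name in FEATURE_NAMES]
            if any(s is None for s in scores):
                continue
            rows.append(scores)
            labels.append(p.responder)
        return cls(X=np.array(rows, dtype=float), y=np.array(labels, dtype=bool))


class SingleRoundTreeModel:
    """One boosting round of a depth-limited tree: a monotone risk ranker."""

    def __init__(self, booster: xgb.Booster):
        self._booster = booster

    def predict_risk(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._booster.predict(xgb.DMatrix(X, feature_names=list(FEATURE_NAMES)[: X.shape[1]]))


def train_single_round_model(
    train: FeatureMatrix,
    *,
    max_depth: int = 3,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> SingleRoundTreeModel:
    """Fit a gradient-boosted tree ensemble limited to exactly one round.

    With one round and logistic loss the tree's leaf values are a monotone
    function of the leaf log-odds, so the output serves as a risk score for
    ranking.  Deterministic given the seed.
    """
    if len(np.unique(train.y)) < 2:
        raise IcarError("degenerate_labels", "training set has a single class")
    dtrain = xgb.DMatrix(
        train.X, label=train.y.astype(int), feature_names=list(train.feature_names)
    )
    params = {
        "objective": "binary:logistic",
        "max_depth": int(max_depth),
        "eta": float(learning_rate),
        "base_score": 0.5,
        "tree_method": "exact",
        "nthread": 1,
        "seed": int(seed) % _XGB_SEED_MOD,
        # the single round is the regulariser: no L2 penalty or hessian
        # floor, so splits and leaf values depend only on class proportions
        # (duplicating every row leaves the fitted tree unchanged)
        "lambda": 0.0,
        "min_child_weight": 0.0,
    }
    booster = xgb.train(params, dtrain, num_boost_round=1)
    return SingleRoundTreeModel(booster)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    The probability that a uniformly random positive outranks a uniformly
    random negative, with ties counted 1/2 (midranks).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise IcarError("degenerate_labels", "need both classes to compute an AUC")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cv_auc(
    cohort: FeatureMatrix,
    seed: int = 0,
    *,
    max_depth: int = 3,
    n_splits: int = 3,
    groups=None,
) -> float:
    """Pooled out-of-fold test AUC under stratified 3-fold cross-validation.

    Each fold trains on 2/3 of the cohort and scores the held-out 1/3; the
    held-out risk scores are pooled across folds and summarised with a
    single AUC.  ``groups`` marks rows that are copies of the same original
    patient (as arise under bootstrap resampling); such rows are kept in
    one fold so a model is never tested on a patient it trained on.  When a
    shuffle leaves a training fold single-class, or a fold empty, the split
    is retried with a fresh shuffle (up to 10 times) before giving up.
    """
    n_pos = int(cohort.y.sum())
    n_neg = cohort.n - n_pos
    if cohort.n < 2 * n_splits or min(n_pos, n_neg) < n_splits:
        raise IcarError(
            "unsplittable_cohort",
            f"cannot stratify n={cohort.n} ({n_pos} pos / {n_neg} neg) into {n_splits} folds",
        )
    y_int = cohort.y.astype(int)
    for attempt in range(10):
        state = (seed + attempt) % _XGB_SEED_MOD
        if groups is None:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=state)
            folds = skf.split(cohort.X, y_int)
        else:
            skf = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=state)
            folds = skf.split(cohort.X, y_int, groups=np.asarray(groups))
        oof = np.full(cohort.n, np.nan)
        ok = True
        for train_idx, test_idx in folds:
            if len(test_idx) == 0 or len(np.unique(y_int[train_idx])) < 2:
                ok = False
                break
            model = train_single_round_model(
                FeatureMatrix(cohort.X[train_idx], cohort.y[train_idx], cohort.feature_names),
                max_depth=max_depth,
                seed=seed,
            )
            oof[test_idx] = model.predict_risk(cohort.X[test_idx])
        if ok and not np.isnan(oof).any():
            return roc_auc(oof, cohort.y)
    raise IcarError("unsplittable_cohort", "no stratified split with both classes in every training fold")


@dataclass(frozen=True)
class PredictiveEvalResult:
    """Distribution of test AUCs at one resampled cohort size."""

    cohort_size: int
    auc_per_repeat: tuple[float, ...]
    seed: int

    @property
    def min_auc(self) -> float:
        return float(min(self.auc_per_repeat))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_repeat))


def _stratified_bootstrap(rng: np.random.Generator, y: np.ndarray, size: int, min_per_class: int = 3) -> np.ndarray:
    """Indices of a size-``size`` bootstrap preserving the class balance.

    Class counts are the rounded proportional shares, floored at
    ``min_per_class`` so the draw stays 3-fold-splittable.  A draw whose
    class collapses onto a single distinct source patient cannot be split
    with patient-grouped folds, so such draws are rejected and redrawn.
    """
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    n_pos = int(round(size * pos_idx.size / y.size))
    n_pos = min(max(n_pos, min_per_class), size - min_per_class)
    for _ in range(100):
        take_pos = rng.choice(pos_idx, size=n_pos, replace=True)
        take_neg = rng.choice(neg_idx, size=size - n_pos, replace=True)
        if len(np.unique(take_pos)) >= 2 and len(np.unique(take_neg)) >= 2:
            return np.concatenate([take_pos, take_neg])
    raise IcarError("unsplittable_cohort", "source cohort too degenerate to bootstrap")


def cohort_sampling_curve(
    cohort: FeatureMatrix,
    sizes=PROTOCOL_SIZES,
    repeats: int = 100,
    seed: int = 0,
    *,
    max_depth: int = 3,
    allow_small: bool = False,
) -> list[PredictiveEvalResult]:
    """Repeat the CV protocol over bootstrap cohorts of each requested size.

    For every size, ``repeats`` cohorts are drawn by stratified sampling
    *with replacement* from the source cohort (so size == n draws are still
    perturbed resamples, not the identity) and each is evaluated with
    :func:`cv_auc`.  Bit-reproducible from ``seed``.
    """
    sizes = [int(s) for s in sizes]
    if any(s < min(PROTOCOL_SIZES) for s in sizes) and not allow_small:
        raise IcarError("size_out_of_protocol", f"sizes below {min(PROTOCOL_SIZES)} are outside the protocol")
    if len(np.unique(cohort.y)) < 2:
        raise IcarError("degenerate_labels", "source cohort has a single class")
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        aucs = []
        for _ in range(repeats):
            idx = _stratified_bootstrap(rng, cohort.y, size)
            sub = FeatureMatrix(cohort.X[idx], cohort.y[idx], cohort.feature_names)
            cv_seed = int(rng.integers(0, _XGB_SEED_MOD))
            # fold by original patient identity: bootstrap copies of one
            # patient must never straddle a train/test boundary
            aucs.append(cv_auc(sub, seed=cv_seed, max_depth=max_depth, groups=idx))
        out.append(PredictiveEvalResult(cohort_size=size, auc_per_repeat=tuple(aucs), seed=seed))
    return out


def curve_to_frame(results: list[PredictiveEvalResult]) -> pd.DataFrame:
    """Long-form (size, repeat, auc) table for export."""
    rows = [
        {"cohort_size": r.cohort_size, "repeat": i, "auc": a}
        for r in results
        for i, a in enumerate(r.auc_per_repeat)
    ]
    return pd.DataFrame(rows, columns=["cohort_size", "repeat", "auc"])
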