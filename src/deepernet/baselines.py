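"""Classical machine-learning benchmark harness.

Five models — SVM (RBF), random forest, k-nearest neighbours, logistic
regression and a decision tree — are each tuned by an inner grid search on
the training folds only and evaluated with five-fold cross-validation.
Features are MinMax-scaled to [0, 1] with scaler parameters fitted on the
training rows alone (test rows may fall outside [0, 1]; no clipping), which
keeps the evaluation leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import EvalReport

logger = logging.getLogger(__name__)

#: Hyper-parameter grids.  The published study tuned by grid search without
#: printing its grids; these are small standard defaults.
DEFAULT_GRIDS: dict[str, dict] = {
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "KNN": {"n_neighbors": [3, 5, 11]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "DT": {"max_depth": [None, 5, 10]},
}


def _make_estimator(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# MinMax scaling
# ---------------------------------------------------------------------------

def minmax_fit(train_features: np.ndarray) -> MinMaxScaler:
    """Fit a [0, 1] MinMax scaler on the training rows only.

    Constant columns are mapped to 0 (and logged)."""
    train_features = np.asarray(train_features, dtype=float)
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train_features)
    const = np.nonzero(scaler.data_range_ == 0)[0]
    if len(const):
        logger.warning("constant training column(s) %s map to 0",
                       const.tolist())
    return scaler


def minmax_apply(scaler: MinMaxScaler, features: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler; out-of-range test values are not clipped."""
    return scaler.transform(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# Cross-validation splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVSplit:
    """Per-segment fold assignment (0..n_folds-1)."""

    folds: np.ndarray
    n_folds: int
    rng_seed: int
    grouping: str = "segment"

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.folds == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.folds != fold)[0]


def make_cv_split(n: int, n_folds: int = 5, rng_seed: int = 0,
                  groups: np.ndarray | None = None) -> CVSplit:
    """Randomly shuffled near-equal folds (sizes differ by at most 1).

    With ``groups`` (e.g. subject ids), whole groups are dealt round-robin
    into folds so no group straddles a train/test boundary.
    """
    rng = np.random.default_rng(rng_seed)
    folds = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            folds[chunk] = f
        grouping = "segment"
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        order = rng.permutation(len(uniq))
        for rank, gi in enumerate(order):
            folds[groups == uniq[gi]] = rank % n_folds
        grouping = "subject"
    return CVSplit(folds=folds, n_folds=n_folds, rng_seed=int(rng_seed),
                   grouping=grouping)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def _scores(est, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class, or a margin mapped through a
    logistic squashing for models without native probabilities."""
    if hasattr(est, "predict_proba"):
        try:
            return est.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    margin = est.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


def run_baselines(
    features: np.ndarray,
    labels: np.ndarray,
    split: CVSplit,
    grids: dict[str, dict] | None = None,
    rng_seed: int = 0,
    inner_cv: int = 3,
) -> dict[str, EvalReport]:
    """Grid-searched five-model comparison under an outer CV split.

    For every outer fold, the MinMax scaler and the grid search see only the
    training rows; the selected model is then scored on the held-out fold.
    Raises if any training fold is single-class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    grids = grids or DEFAULT_GRIDS
    reports = {name: EvalReport() for name in grids}

    for fold in range(split.n_folds):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training fold {fold} contains a single class")
        scaler = minmax_fit(X[tr])
        Xtr, Xte = minmax_apply(scaler, X[tr]), minmax_apply(scaler, X[te])
        for name, grid in grids.items():
            gs = GridSearchCV(_make_estimator(name, rng_seed), grid,
                              cv=inner_cv, scoring="accuracy", n_jobs=None)
            gs.fit(Xtr, y[tr])
            reports[name].add(y[te], _scores(gs.best_estimator_, Xte))
    return reports
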