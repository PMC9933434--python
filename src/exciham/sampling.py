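"""Structure selection and evaluation scores.

Farthest point sampling (FPS) greedily picks configurations that maximize
the minimum distance to the already-selected set — used to sample the
range of MM potentials a pigment experiences when choosing training/test
structures.  Scores are the mean absolute error and the squared Pearson
correlation, evaluated with seeded k-fold cross-validation; a
learning-curve mode refits on nested subsets of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold


def farthest_point_sampling(points, k: int, start_index: int = 0,
                            metric: str = "euclidean") -> np.ndarray:
    """Greedy maximin selection of ``k`` indices.

    Each new index maximizes the minimum distance to the selected set;
    ties break toward the lowest index, so the trace is deterministic
    given ``start_index``.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n} points")
    if not 0 <= start_index < n:
        raise ValueError("invalid start index")
    selected = [start_index]
    mindist = cdist(X, X[[start_index]], metric=metric).ravel()
    for _ in range(k - 1):
        mindist[selected] = -np.inf
        nxt = int(np.argmax(mindist))  # argmax takes the first (lowest) index on ties
        selected.append(nxt)
        mindist = np.minimum(mindist, cdist(X, X[[nxt]], metric=metric).ravel())
    return np.asarray(selected)


def mae(pred, target) -> float:
    """Mean absolute error (same units as the inputs)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(p - t)))


class UndefinedScoreError(ValueError):
    """Correlation undefined: one of the vectors has zero variance."""


def r_squared(pred, target) -> float:
    """Squared Pearson correlation coefficient in [0, 1]."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    sp, st = p.std(), t.std()
    if sp == 0 or st == 0:
        raise UndefinedScoreError("zero variance in predictions or targets")
    r = float(np.mean((p - p.mean()) * (t - t.mean())) / (sp * st))
    return min(r * r, 1.0)


def _take(data, idx):
    idx = np.asarray(idx)
    if hasattr(data, "take") and not isinstance(data, np.ndarray):
        return data.take(idx)
    if isinstance(data, np.ndarray):
        return data[idx]
    return [data[i] for i in idx]


@dataclass(frozen=True)
class CVReport:
    """Per-fold scores with mean and twice-the-standard-deviation bands."""

    fold_mae: np.ndarray
    fold_r2: np.ndarray
    n_train: int

    @property
    def mae_mean(self) -> float:
        return float(self.fold_mae.mean())

    @property
    def mae_band(self) -> float:
        return float(2.0 * self.fold_mae.std())

    @property
    def r2_mean(self) -> float:
        return float(self.fold_r2.mean())

    @property
    def r2_band(self) -> float:
        return float(2.0 * self.fold_r2.std())


def cross_validate(trainer, data, targets, n_folds: int = 5, seed: int = 0) -> CVReport:
    """Seeded k-fold CV of a trainer callable.

    ``trainer(data_train, y_train)`` must return a callable
    ``predict(data_test) -> array``.  Folds are a seeded shuffle split, so
    the report is deterministic given ``seed``.  A fold whose predictions
    (or targets) are constant gets an r² of NaN rather than an error.
    """
    y = np.asarray(targets, dtype=float)
    n = y.shape[0]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    maes, r2s = [], []
    for train_idx, test_idx in kf.split(np.arange(n)):
        predict = trainer(_take(data, train_idx), y[train_idx])
        pred = np.asarray(predict(_take(data, test_idx)), dtype=float)
        maes.append(mae(pred, y[test_idx]))
        try:
            r2s.append(r_squared(pred, y[test_idx]))
        except UndefinedScoreError:
            r2s.append(np.nan)
    return CVReport(fold_mae=np.asarray(maes), fold_r2=np.asarray(r2s), n_train=n)


def learning_curve(trainer, data, targets, sizes, n_folds: int = 5, seed: int = 0):
    """CV reports at nested training subsets of the given sizes.

    Subsets are drawn without replacement with a seeded generator and are
    nested (smaller ⊂ larger) to reduce the variance of the curve.
    """
    y = np.asarray(targets, dtype=float)
    n = y.shape[0]
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > n:
        raise ValueError("largest size exceeds the number of samples")
    order = np.random.default_rng(seed).permutation(n)
    reports = {}
    for s in sizes:
        idx = order[:s]
        reports[s] = cross_validate(
            trainer, _take(data, idx), y[idx], n_folds=n_folds, seed=seed
        )
    return reports
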