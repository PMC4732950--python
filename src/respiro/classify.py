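"""Weighted sparse-representation classification of complexity profiles.

A test subject's feature vector y is represented as a sparse combination of
the training subjects' vectors (columns of A), with each training sample k
penalized by a weight w_k proportional to its Minkowski distance from y —
near neighbors are cheap to use, far ones expensive.  The exact weighted
l0 program is NP-hard; it is solved here by weighted greedy matching
pursuit with a least-squares refit on the selected support (a weighted-l1
route via scipy's lasso-style solver is available behind a flag).  The
predicted class minimizes the class-restricted reconstruction residual.

Evaluation is by leave-one-out cross-validation with fold-internal feature
standardization, and features are ranked by sequential forward selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, CohortDataset

_EPS = 1e-6

#: Binary diagnostic groupings of the four-group cohort.
TASKS: dict[str, dict[str, str]] = {
    "asthma_vs_healthy": {"CAA": "Asthma", "UAA": "Asthma", "UNAA": "Asthma"},
    "uncontrolled_vs_controlled": {"UAA": "Uncontrolled", "UNAA": "Uncontrolled",
                                   "CAA": "Controlled"},
    "nonatopic_vs_atopic": {"UNAA": "NonAtopic", "CAA": "Atopic", "UAA": "Atopic"},
}

#: The positive (disease/target) class of each task.
TASK_POSITIVE: dict[str, str] = {
    "asthma_vs_healthy": "Asthma",
    "uncontrolled_vs_controlled": "Uncontrolled",
    "nonatopic_vs_atopic": "NonAtopic",
}

#: Which subjects participate in each task (asthma tasks exclude healthy).
TASK_KEEP: dict[str, tuple] = {
    "asthma_vs_healthy": ("Healthy", "CAA", "UAA", "UNAA"),
    "uncontrolled_vs_controlled": ("CAA", "UAA", "UNAA"),
    "nonatopic_vs_atopic": ("CAA", "UAA", "UNAA"),
}

#: Named feature combinations.
FEATURE_PRESETS: dict[str, tuple] = {
    "ibi_all": ("DFA_IBI", "SampEn_IBI", "LLE_IBI"),
    "lv_all": ("DFA_LV", "SampEn_LV", "LLE_LV"),
    "dfa_both": ("DFA_IBI", "DFA_LV"),
    "sampen_both": ("SampEn_IBI", "SampEn_LV"),
    "lle_both": ("LLE_IBI", "LLE_LV"),
    "all": FEATURE_NAMES,
}


@dataclass(frozen=True)
class SparseFit:
    coefficients: np.ndarray
    weights: np.ndarray
    residuals: dict
    predicted: str
    support: tuple


@dataclass
class ConfusionSummary:
    classes: list
    matrix: pd.DataFrame
    accuracy: float
    predictions: pd.Series
    warnings: list = field(default_factory=list)

    def binary_counts(self, positive: str) -> dict:
        """TP/FN/TN/FP counts treating ``positive`` as the target class."""
        truth = self.predictions.index.map(self._truth)
        pred = self.predictions
        tp = int(((truth == positive) & (pred == positive)).sum())
        fn = int(((truth == positive) & (pred != positive)).sum())
        tn = int(((truth != positive) & (pred != positive)).sum())
        fp = int(((truth != positive) & (pred == positive)).sum())
        return {"tp": tp, "fn": fn, "tn": tn, "fp": fp}

    def _truth(self, sid):
        return self._truth_map[sid]


def minkowski_weights(y: np.ndarray, A: np.ndarray, p: float = 2.0) -> np.ndarray:
    """Per-training-sample penalty weights from Minkowski-p distances to y.

    Distances are rescaled linearly to [eps, 1] so the nearest sample gets
    the minimum penalty eps = 1e-6.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    if y.shape[0] != A.shape[0]:
        raise ValueError("dimension mismatch between y and columns of A")
    d = np.sum(np.abs(A - y[:, None]) ** p, axis=0) ** (1.0 / p)
    lo, hi = d.min(), d.max()
    if hi - lo <= 1e-9 * max(hi, 1.0):  # effectively equidistant samples
        return np.ones_like(d)
    return _EPS + (1.0 - _EPS) * (d - lo) / (hi - lo)


def _greedy_weighted_pursuit(A: np.ndarray, y: np.ndarray, w: np.ndarray,
                             budget: int, tol: float = 1e-10) -> np.ndarray:
    """Weighted matching pursuit: pick columns maximizing |corr|/w, LS refit."""
    n = A.shape[1]
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    support: list[int] = []
    coef = np.zeros(n)
    resid = y.copy()
    for _ in range(min(budget, n)):
        score = np.abs(A.T @ resid) / norms / w
        score[support] = -np.inf
        k = int(np.argmax(score))
        if not np.isfinite(score[k]):
            break
        support.append(k)
        sub = A[:, support]
        sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
        coef = np.zeros(n)
        coef[support] = sol
        resid = y - sub @ sol
        if np.linalg.norm(resid) <= tol:
            break
    return coef


def _weighted_l1(A: np.ndarray, y: np.ndarray, w: np.ndarray,
                 alpha: float = 1e-3, n_iter: int = 500) -> np.ndarray:
    """Coordinate-descent weighted lasso surrogate for the l0 objective."""
    n = A.shape[1]
    coef = np.zeros(n)
    col_sq = np.einsum("ij,ij->j", A, A)
    col_sq[col_sq == 0] = 1.0
    resid = y.copy()
    for _ in range(n_iter):
        max_delta = 0.0
        for k in range(n):
            old = coef[k]
            rho = A[:, k] @ resid + col_sq[k] * old
            thr = alpha * w[k] * len(y)
            new = np.sign(rho) * max(abs(rho) - thr, 0.0) / col_sq[k]
            if new != old:
                resid += A[:, k] * (old - new)
                coef[k] = new
                max_delta = max(max_delta, abs(new - old))
        if max_delta < 1e-10:
            break
    return coef


def wsrc_fit_predict(A: np.ndarray, labels, y: np.ndarray,
                     sparsity_budget: Optional[int] = None, p: float = 2.0,
                     solver: str = "pursuit") -> SparseFit:
    """Classify y by minimal class-restricted reconstruction residual.

    ``A`` is features x training-samples (columns standardized with training
    statistics, as is ``y``).  Ties in the residual are broken toward the
    class with larger total |coefficient| mass, then lexicographically.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    n = A.shape[1]
    if not np.any(y):
        raise ValueError("all-zero test vector")
    if sparsity_budget is None:
        sparsity_budget = min(10, max(1, -(-n // 4)))
    if sparsity_budget < 1 or sparsity_budget > n:
        raise ValueError("sparsity budget must be in [1, n_train]")
    w = minkowski_weights(y, A, p=p)
    if solver == "pursuit":
        coef = _greedy_weighted_pursuit(A, y, w, sparsity_budget)
    elif solver == "l1":
        coef = _weighted_l1(A, y, w)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    classes = sorted(set(labels.tolist()))
    residuals = {}
    mass = {}
    norm_y = float(np.linalg.norm(y))
    for c in classes:
        mask = labels == c
        xc = np.where(mask, coef, 0.0)
        # a class never scores worse than the empty representation
        residuals[c] = min(float(np.linalg.norm(y - A @ xc)), norm_y)
        mass[c] = float(np.abs(xc).sum())
    best = min(classes, key=lambda c: (round(residuals[c], 12), -mass[c], c))
    return SparseFit(coefficients=coef, weights=w, residuals=residuals,
                     predicted=str(best),
                     support=tuple(int(i) for i in np.flatnonzero(coef)))


def _standardize_fold(train: np.ndarray, test: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Standardize features with training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def loocv_wsrc(data: CohortDataset, task: Optional[str] = None,
               sparsity_budget: Optional[int] = None, p: float = 2.0,
               solver: str = "pursuit") -> ConfusionSummary:
    """Leave-one-out cross-validation of the WSRC classifier.

    ``task`` names a binary regrouping from :data:`TASKS` (subjects outside
    the task's groups are dropped); None keeps the original labels.  Each
    fold standardizes features on its n-1 training subjects.
    """
    if task is not None:
        if task not in TASKS:
            raise KeyError(f"unknown task {task!r}; valid: {sorted(TASKS)}")
        keep = data.labels.isin(TASK_KEEP[task])
        data = CohortDataset(data.features[keep], data.labels[keep])
        data = data.relabel(TASKS[task])
    X = data.features.to_numpy(dtype=float)
    yl = data.labels.to_numpy()
    classes = sorted(set(yl.tolist()))
    if len(classes) < 2:
        raise ValueError("classification requires >= 2 classes")
    warnings_list = []
    counts = pd.Series(yl).value_counts()
    if (counts < 2).any():
        warnings_list.append("a class has a single member; its LOOCV fold "
                             "cannot contain it in training")
    preds = []
    for i in range(len(yl)):
        mask = np.ones(len(yl), dtype=bool)
        mask[i] = False
        train, test = _standardize_fold(X[mask], X[i])
        fit = wsrc_fit_predict(train.T, yl[mask], test,
                               sparsity_budget=sparsity_budget, p=p,
                               solver=solver)
        preds.append(fit.predicted)
    pred_s = pd.Series(preds, index=data.features.index, name="predicted")
    matrix = pd.crosstab(pd.Series(yl, index=pred_s.index, name="true"),
                         pred_s).reindex(index=classes, columns=classes,
                                         fill_value=0)
    acc = float((pred_s.to_numpy() == yl).mean())
    summary = ConfusionSummary(classes=classes, matrix=matrix, accuracy=acc,
                               predictions=pred_s, warnings=warnings_list)
    summary._truth_map = dict(zip(pred_s.index, yl))
    return summary


def sequential_forward_selection(data: CohortDataset, task: Optional[str] = None,
                                 criterion: Optional[Callable] = None,
                                 **loocv_kw) -> pd.DataFrame:
    """Greedy forward feature ranking by LOOCV accuracy.

    Starting from the empty set, the feature whose addition maximizes the
    criterion (default: LOOCV-WSRC accuracy) is appended until all features
    are used.  Returns the trajectory with columns ``feature`` (added at
    that step), ``accuracy`` and ``features`` (cumulative tuple); overfitting
    shows up as a trajectory that peaks before all features are in.
    """
    if criterion is None:
        def criterion(subset):
            return loocv_wsrc(data.select(list(subset)), task=task,
                              **loocv_kw).accuracy
    remaining = list(data.feature_names)
    if len(remaining) < 2:
        raise ValueError("need at least 2 features for forward selection")
    chosen: list[str] = []
    records = []
    while remaining:
        scored = [(criterion(chosen + [f]), f) for f in remaining]
        best_acc, best_f = max(scored, key=lambda t: (t[0], -remaining.index(t[1])))
        chosen.append(best_f)
        remaining.remove(best_f)
        records.append({"feature": best_f, "accuracy": best_acc,
                        "features": tuple(chosen)})
    return pd.DataFrame(records)
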