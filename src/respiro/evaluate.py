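"""ROC analysis, exact binomial intervals, diagnostic ratios and
group-difference statistics.

AUC is computed by the trapezoid rule over the full threshold sweep (equal
to the Mann-Whitney concordant-pair fraction with ties counted half), its
standard error by the Hanley-McNeil formula, and sensitivity/specificity
intervals by the exact Clopper-Pearson method.  Four-group comparisons use
one-way ANOVA with Bonferroni post-tests when every group passes a Shapiro
normality check, otherwise Kruskal-Wallis with Dunn's rank post-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    se_auc: float
    ci95: tuple
    best_cutoff: float
    se_at_cutoff: float
    sp_at_cutoff: float
    p_value: float
    flipped: bool


@dataclass(frozen=True)
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    pairwise: dict
    alpha: float = 0.05

    def significant_pairs(self) -> list:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(scores, labels, positive=1, direction: str = "auto") -> ROCResult:
    """ROC over all unique thresholds of a per-subject index.

    ``direction='auto'`` flips the score sign when that raises the AUC above
    0.5 (recorded in ``flipped``); the reported cutoff is on the original
    scale.  The best cutoff maximizes Youden J = Se + Sp - 1, ties resolved
    toward higher specificity.  ``p_value`` tests AUC = 0.5 by a normal
    approximation on the Hanley-McNeil standard error.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def sweep(s):
        thr = np.unique(s)[::-1]
        tpr = np.empty(thr.size + 2)
        fpr = np.empty(thr.size + 2)
        tpr[0] = fpr[0] = 0.0
        for i, t in enumerate(thr, start=1):
            pred = s >= t
            tpr[i] = (pred & (y == 1)).sum() / n_pos
            fpr[i] = (pred & (y == 0)).sum() / n_neg
        tpr[-1] = fpr[-1] = 1.0
        return np.concatenate(([np.inf], thr, [-np.inf])), tpr, fpr

    if direction not in ("auto", "none"):
        raise ValueError("direction must be 'auto' or 'none'")
    thr, tpr, fpr = sweep(scores)
    auc = float(np.trapezoid(tpr, fpr))
    flipped = False
    if direction == "auto" and auc < 0.5:
        thr, tpr, fpr = sweep(-scores)
        auc = float(np.trapezoid(tpr, fpr))
        flipped = True
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    z = (auc - 0.5) / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    youden = tpr - fpr
    # ties toward higher specificity = lower fpr
    best = max(range(len(youden)), key=lambda i: (youden[i], -fpr[i]))
    cutoff = thr[best]
    if np.isfinite(cutoff) and flipped:
        cutoff = -cutoff
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc, se_auc=se,
                     ci95=ci, best_cutoff=float(cutoff),
                     se_at_cutoff=float(tpr[best]), sp_at_cutoff=float(1 - fpr[best]),
                     p_value=p, flipped=flipped)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple:
    """Exact binomial confidence interval for k successes in n trials, in %."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (100.0 * lo, 100.0 * hi)


def diagnostic_metrics(tp: int, fn: int, tn: int, fp: int,
                       conf: float = 0.95) -> dict:
    """Se/Sp/PPV/NPV/LR+/LR- with confidence intervals.

    Proportions get exact Clopper-Pearson intervals (percent); likelihood
    ratios get log-method intervals.  Division by zero yields inf or nan,
    matching the usual reporting conventions for perfect classifiers.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn + tn + fp == 0:
        raise ValueError("all-zero confusion table")
    z = stats.norm.ppf(1 - (1 - conf) / 2)

    def prop(k, n):
        if n == 0:
            return float("nan"), (float("nan"), float("nan"))
        return 100.0 * k / n, clopper_pearson(k, n, conf)

    se, se_ci = prop(tp, tp + fn)
    sp, sp_ci = prop(tn, tn + fp)
    ppv, ppv_ci = prop(tp, tp + fp)
    npv, npv_ci = prop(tn, tn + fn)

    def lr(num_k, num_n, den_k, den_n):
        """Likelihood ratio (num_k/num_n)/(den_k/den_n) with log-method CI."""
        if num_n == 0 or den_n == 0:
            return float("nan"), (float("nan"), float("nan"))
        num = num_k / num_n
        den = den_k / den_n
        if den == 0:
            return float("inf"), (float("nan"), float("inf"))
        ratio = num / den
        if num == 0:
            return 0.0, (0.0, float("nan"))
        se_log = np.sqrt((1 - num) / (num_n * num) + (1 - den) / (den_n * den))
        return ratio, (float(ratio * np.exp(-z * se_log)),
                       float(ratio * np.exp(z * se_log)))

    lr_pos, lr_pos_ci = lr(tp, tp + fn, fp, fp + tn)
    lr_neg, lr_neg_ci = lr(fn, tp + fn, tn, fp + tn)
    return {
        "se": se, "se_ci": se_ci, "sp": sp, "sp_ci": sp_ci,
        "ppv": ppv, "ppv_ci": ppv_ci, "npv": npv, "npv_ci": npv_ci,
        "lr_pos": lr_pos, "lr_pos_ci": lr_pos_ci,
        "lr_neg": lr_neg, "lr_neg_ci": lr_neg_ci,
        "counts": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    }


def _dunn_posthoc(groups: dict, adjust: bool = True) -> dict:
    """Dunn's z-test on mean ranks with tie correction, Bonferroni-adjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        size = len(groups[g])
        mean_ranks[g] = ranks[start:start + size].mean()
        sizes[g] = size
        start += size
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for a, b in combinations(labels, 2):
        sd = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        zval = abs(mean_ranks[a] - mean_ranks[b]) / sd if sd > 0 else 0.0
        p = 2 * stats.norm.sf(zval)
        out[(a, b)] = min(1.0, p * m) if adjust else p
    return out


def group_compare(values, groups, method: str = "auto",
                  alpha: float = 0.05) -> GroupComparison:
    """Compare an index across groups with a matching post-hoc test.

    ``method='auto'`` runs one-way ANOVA + Bonferroni-adjusted pairwise
    t-tests when every group passes Shapiro normality at 0.05, otherwise
    Kruskal-Wallis + Dunn's post-test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: values[groups == g] for g in labels}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if np.ptp(values) == 0:
        # no variation anywhere: nothing distinguishes the groups
        pairwise = {pair: 1.0 for pair in combinations(labels, 2)}
        return GroupComparison(method="kruskal_dunn", statistic=0.0,
                               p_value=1.0, pairwise=pairwise, alpha=alpha)
    if method == "auto":
        normal = all(v.size >= 3 and np.ptp(v) > 0
                     and stats.shapiro(v).pvalue > 0.05 for v in data.values())
        method = "anova_bonferroni" if normal else "kruskal_dunn"
    m = len(labels) * (len(labels) - 1) // 2
    if method == "anova_bonferroni":
        stat, p = stats.f_oneway(*data.values())
        pairwise = {}
        for a, b in combinations(labels, 2):
            _, pr = stats.ttest_ind(data[a], data[b])
            pairwise[(a, b)] = min(1.0, float(pr) * m)
    elif method == "kruskal_dunn":
        stat, p = stats.kruskal(*data.values())
        pairwise = _dunn_posthoc(data)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(method=method, statistic=float(stat),
                           p_value=float(p), pairwise=pairwise, alpha=alpha)
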