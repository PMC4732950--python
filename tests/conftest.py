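"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths: entropy is
counted by explicit template loops, DFA fluctuations by per-box arithmetic,
AUC by concordant-pair enumeration, and the logistic-map Lyapunov exponent
by its analytic orbit average.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from respiro.types import CohortDataset


# ---------------------------------------------------------------------------
# Oracles

def brute_sampen(x: np.ndarray, m: int, r: float) -> float:
    """O(N^2) sample entropy by direct template comparison."""
    x = np.asarray(x, dtype=float)
    tol = r * x.std(ddof=1)
    n = x.size

    def count(length: int) -> int:
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def brute_cross_sampen(xa: np.ndarray, xb: np.ndarray, m: int, r: float) -> float:
    """O(N^2) cross-sample entropy: templates from xa matched in xb."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    tol = r * math.sqrt((xa.std(ddof=1) ** 2 + xb.std(ddof=1) ** 2) / 2.0)
    n = xa.size

    def count(length: int) -> int:
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if max(abs(xa[i + k] - xb[j + k]) for k in range(length)) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def brute_dfa_fluctuation(x: np.ndarray, n: int, order: int = 1) -> float:
    """RMS detrended fluctuation at one box size, box by box."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())
    n_boxes = profile.size // n
    sq = []
    for b in range(n_boxes):
        seg = profile[b * n:(b + 1) * n]
        t = np.arange(n, dtype=float)
        coeffs = np.polyfit(t, seg, order)
        resid = seg - np.polyval(coeffs, t)
        sq.extend(resid**2)
    return math.sqrt(np.mean(sq))


def pair_count_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the concordant-pair fraction, ties counted half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def logistic_lyapunov_oracle(r: float, x0: float, n: int = 5000,
                             burn_in: int = 100) -> float:
    """Analytic orbit average of ln|r(1-2x)| for the logistic map."""
    x = x0
    for _ in range(burn_in):
        x = r * x * (1.0 - x)
    acc = 0.0
    for _ in range(n):
        acc += math.log(abs(r * (1.0 - 2.0 * x)))
        x = r * x * (1.0 - x)
    return acc / n


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160129)


def make_feature_cohort(group_means: dict, n_per_group: int, sd: float,
                        seed: int, feature_names=("f1", "f2")) -> CohortDataset:
    """Gaussian feature-table cohort: group label -> per-feature mean."""
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for g, means in group_means.items():
        for i in range(n_per_group):
            rows.append({f: m + sd * rng.standard_normal()
                         for f, m in zip(feature_names, means)})
            labels.append(g)
            ids.append(f"{g}_{i}")
    feats = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    return CohortDataset(feats, pd.Series(labels, index=feats.index, name="group"))


@pytest.fixture(scope="session")
def separated_cohort():
    """Two classes 10 SD apart: any sane classifier scores 100%."""
    return make_feature_cohort({"A": (0.0, 0.0), "B": (10.0, 10.0)},
                               n_per_group=8, sd=1.0, seed=42)
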