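"""Nonlinear complexity indices for breath-by-breath series.

Four indices quantify complementary aspects of breathing-pattern dynamics:

* **DFA** — detrended fluctuation analysis; the scaling exponent alpha
  measures long-range correlation (0.5 uncorrelated, 1.0 1/f fractal
  dynamics, 1.5 integrated random walk).
* **SampEn** — sample entropy; the negative log conditional probability
  that sequences matching for m points (within tolerance r, Chebyshev
  distance, self-matches excluded) still match at point m+1.  Lower values
  mean more regular dynamics.
* **Cross-SampEn** — the two-series analogue, quantifying asynchrony
  between the interval and volume series; lower values mean stronger
  synchronization.
* **LLE** — largest Lyapunov exponent by the Rosenstein nearest-neighbor
  divergence method, with delay chosen by average mutual information and
  embedding dimension by false nearest neighbors.  Positive values indicate
  sensitive dependence on initial conditions.

All indices are computed on z-normalized series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import summary_stats, znormalize
from .types import ComplexityProfile, Series


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis

@dataclass(frozen=True)
class DFAResult:
    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    r_squared: float


def _auto_box_sizes(n: int, n_boxes: int = 15) -> np.ndarray:
    """~15 log-spaced integer box sizes from 4 to N/4, duplicates removed."""
    if n < 64:
        raise ValueError("series too short for automatic box sizes (need >= 64)")
    sizes = np.unique(np.round(np.geomspace(4, n // 4, n_boxes)).astype(int))
    return sizes


def dfa(series: Series, box_sizes: Optional[Sequence[int]] = None,
        order: int = 1) -> DFAResult:
    """DFA of a series: integrate, detrend per box, fit log F(n) vs log n.

    The mean-subtracted series is integrated; for each box size n the
    profile is cut into floor(N/n) non-overlapping boxes, a least-squares
    polynomial of the given order (default 1) is removed per box, and F(n)
    is the RMS of the residuals.  alpha is the slope of the least-squares
    line through (log n, log F(n)).
    """
    x = series.values
    if x.std(ddof=1) == 0:
        raise ValueError("constant series has no fluctuations to analyze")
    sizes = (_auto_box_sizes(x.size) if box_sizes is None
             else np.asarray(sorted(set(int(b) for b in box_sizes))))
    if sizes.size < 4:
        raise ValueError("need at least 4 box sizes for a stable log-log fit")
    if sizes.min() < 4:
        raise ValueError("box sizes must be >= 4")
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(sizes.size, dtype=float)
    t_full = np.arange(x.size, dtype=float)
    for i, n in enumerate(sizes):
        n_boxes = profile.size // n
        seg = profile[: n_boxes * n].reshape(n_boxes, n)
        t = t_full[:n]
        # vectorized per-box polynomial detrend
        V = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(V, seg.T, rcond=None)
        resid = seg.T - V @ coef
        flucts[i] = np.sqrt(np.mean(resid**2))
    log_n = np.log10(sizes)
    log_f = np.log10(flucts)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    fit = slope * log_n + intercept
    ss_res = float(np.sum((log_f - fit) ** 2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DFAResult(alpha=float(slope), box_sizes=sizes, fluctuations=flucts,
                     r_squared=r2)


# ---------------------------------------------------------------------------
# Sample entropy and cross-sample entropy

@dataclass(frozen=True)
class EntropyParams:
    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")


def _template_matrix(x: np.ndarray, length: int, m: int) -> np.ndarray:
    """The first N-m templates of the given length as a matrix.

    Both the m- and the (m+1)-point counts run over the same N-m template
    start indices, as the canonical definition requires.
    """
    n = x.size
    return np.lib.stride_tricks.sliding_window_view(x, length)[: n - m]


def _chebyshev_match_counts(templ_a: np.ndarray, templ_b: np.ndarray,
                            tol: float, exclude_self: bool) -> int:
    """Number of ordered template pairs within Chebyshev distance tol.

    Counted exactly with a KD-tree under the max norm (distance <= tol,
    matching the canonical tolerance convention); self pairs (i == j over a
    shared index set) are subtracted when requested.
    """
    tree_a = cKDTree(templ_a)
    tree_b = tree_a if templ_b is templ_a else cKDTree(templ_b)
    total = int(tree_a.count_neighbors(tree_b, tol, p=np.inf))
    if exclude_self:
        total -= templ_a.shape[0]
    return total


def sample_entropy(series: Series, params: EntropyParams = EntropyParams()
                   ) -> float:
    """SampEn = -ln(A/B) with tolerance r times the series sample SD.

    A counts (m+1)-point template matches, B counts m-point matches, over
    distinct index pairs (self-matches excluded).  Returns +inf when no
    (m+1)-match exists (flagged regularity floor on short regular series).
    """
    x = series.values
    m = params.m
    if x.size < m + 2:
        raise ValueError(f"series too short for m={m} (need >= {m + 2})")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series has undefined sample entropy")
    tol = params.r * sd
    tm = _template_matrix(x, m, m)
    tm1 = _template_matrix(x, m + 1, m)
    b = _chebyshev_match_counts(tm, tm, tol, exclude_self=True)
    a = _chebyshev_match_counts(tm1, tm1, tol, exclude_self=True)
    if b == 0:
        raise ValueError("no m-point template matches; r too small for this series")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def cross_sample_entropy(a: Series, b: Series,
                         params: EntropyParams = EntropyParams(),
                         symmetric: bool = False) -> float:
    """Cross-SampEn between two series: templates from ``a`` matched in ``b``.

    The tolerance is r times the pooled sample SD of the two inputs (equal
    to r when both are z-normalized).  There is no self-match concept.  With
    ``symmetric=True`` the mean of the two directed statistics is returned.
    """
    xa, xb = a.values, b.values
    if xa.size != xb.size:
        raise ValueError("series must have equal length (align before calling)")
    m = params.m
    if xa.size < m + 2:
        raise ValueError(f"series too short for m={m}")
    sda, sdb = xa.std(ddof=1), xb.std(ddof=1)
    if sda == 0 or sdb == 0:
        raise ValueError("constant input series")
    tol = params.r * float(np.sqrt((sda**2 + sdb**2) / 2.0))

    def directed(u: np.ndarray, v: np.ndarray) -> float:
        bm = _chebyshev_match_counts(_template_matrix(u, m, m),
                                     _template_matrix(v, m, m), tol, False)
        am = _chebyshev_match_counts(_template_matrix(u, m + 1, m),
                                     _template_matrix(v, m + 1, m), tol, False)
        if bm == 0:
            raise ValueError("no m-point cross matches; r too small")
        if am == 0:
            return float("inf")
        return float(-np.log(am / bm))

    if not symmetric:
        return directed(xa, xb)
    return float(np.mean([directed(xa, xb), directed(xb, xa)]))


# ---------------------------------------------------------------------------
# Embedding-parameter selection

@dataclass(frozen=True)
class EmbeddingParams:
    m: int
    tau: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding dimension and delay must be >= 1")


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Mutual information (nats) from a joint histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def average_mutual_information(series: Series, max_lag: int = 20,
                               bins: Optional[int] = None) -> tuple[int, np.ndarray]:
    """Delay selection: first local minimum of the lagged mutual information.

    Returns (tau, I) where I[k-1] is the mutual information at lag k.  If the
    series decorrelates immediately (I(1) already a small fraction of the
    marginal entropy), tau = 1; failing a local minimum, the first lag with
    I < I(1)/e is used; failing that, the minimizing lag.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    x = series.values
    if x.size < 10 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if bins is None:
        bins = max(8, int(round(np.sqrt(x.size / 5))))
    mi = np.array([_histogram_mi(x[:-k], x[k:], bins) for k in range(1, max_lag + 1)])
    h_marginal = _histogram_mi(x, x, bins)  # = marginal entropy
    # histogram MI of independent samples is biased up by ~ (bins-1)^2 / 2N
    bias_floor = (bins - 1) ** 2 / (2.0 * x.size)
    floor = max(2.0 * bias_floor, 0.05 * h_marginal)

    def _at_floor(value: float) -> bool:
        return value <= floor

    if _at_floor(mi[0]):
        return 1, mi
    for k in range(1, mi.size - 1):
        if mi[k] < mi[k - 1] and mi[k] <= mi[k + 1]:
            # a dip at the estimator's bias floor is decay, not rhythm
            return (1 if _at_floor(mi[k]) else k + 1), mi
    below = np.flatnonzero(mi < mi[0] / np.e)
    if below.size:
        k = int(below[0])
        return (1 if _at_floor(mi[k]) else k + 1), mi
    return int(np.argmin(mi) + 1), mi


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("series too short for this embedding")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def false_nearest_neighbors(series: Series, tau: int, max_dim: int = 10,
                            rtol: float = 15.0, atol: float = 2.0,
                            threshold: float = 0.01
                            ) -> tuple[int, np.ndarray, bool]:
    """Embedding dimension by the false-nearest-neighbor criterion.

    For each dimension d, each embedded point's nearest neighbor is checked
    after appending the (d+1)-th coordinate: the neighbor is false if the
    extra separation exceeds ``rtol`` times the d-dimensional distance, or
    if the (d+1)-dimensional distance exceeds ``atol`` times the series SD.
    Returns (m, fractions, capped): the smallest d with false fraction below
    ``threshold``, or ``max_dim`` with ``capped=True`` for noise-like series
    that never embed.
    """
    x = series.values
    if x.size < 50 * max_dim:
        raise ValueError("series too short for FNN up to max_dim")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series cannot be embedded")
    fractions = np.empty(max_dim, dtype=float)
    for d in range(1, max_dim + 1):
        emb = _embed(x, d, tau)
        n_next = x.size - d * tau  # vectors that still have a next coordinate
        if n_next < 10:
            fractions[d - 1:] = np.nan
            break
        emb = emb[:n_next]
        tree = cKDTree(emb)
        dist, nbr = tree.query(emb, k=2)
        dist, nbr = dist[:, 1], nbr[:, 1]
        i = np.arange(n_next)
        extra = np.abs(x[i + d * tau] - x[nbr + d * tau])
        dist_next = np.sqrt(dist**2 + extra**2)
        # exactly coincident neighbors (dist 0) are false only if they split
        with np.errstate(divide="ignore"):
            ratio = np.where(dist > 0, extra / np.where(dist > 0, dist, 1.0),
                             np.where(extra > 0, np.inf, 0.0))
        false = (ratio > rtol) | (dist_next / sd > atol)
        fractions[d - 1] = false.mean()
        if fractions[d - 1] < threshold:
            return d, fractions[:d], False
    return max_dim, fractions, True


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein)

@dataclass(frozen=True)
class LLEResult:
    lle: float
    divergence_curve: np.ndarray
    fit_range: tuple
    embedding: EmbeddingParams
    theiler: int


def _mean_period(x: np.ndarray) -> int:
    """Mean period = reciprocal of the power-weighted mean frequency."""
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size)
    power = spec[1:].sum()
    if power == 0:
        return 1
    mean_freq = float((spec[1:] * freqs[1:]).sum() / power)
    return max(1, int(round(1.0 / mean_freq)))


def largest_lyapunov(series: Series,
                     embedding: Optional[EmbeddingParams] = None,
                     theiler: Optional[int] = None,
                     fit_range: tuple = (1, 10),
                     max_steps: Optional[int] = None) -> LLEResult:
    """Rosenstein estimate of the largest Lyapunov exponent.

    Each embedded point is paired with its nearest neighbor at least
    ``theiler`` samples away (auto: the dominant spectral period); the mean
    log-separation curve y(i) is tracked over i steps and the LLE is the
    least-squares slope of y over ``fit_range`` (default steps 1-10).  The
    time unit is one breath (Delta t = 1), so the exponent is per breath.
    """
    x = series.values
    if embedding is None:
        max_lag = min(20, x.size // 10)
        tau, _ = average_mutual_information(series, max_lag=max(2, max_lag))
        max_dim = max(2, min(10, x.size // 50))
        m, _, _ = false_nearest_neighbors(series, tau, max_dim=max_dim)
        embedding = EmbeddingParams(m=m, tau=tau)
    emb = _embed(x, embedding.m, embedding.tau)
    n_vec = emb.shape[0]
    if n_vec < 100:
        raise ValueError("need at least 100 embedded vectors")
    if theiler is None:
        theiler = min(_mean_period(x), n_vec // 10)
    lo, hi = fit_range
    if max_steps is None:
        max_steps = max(hi, 10)
    max_steps = min(max_steps, n_vec - 1)

    tree = cKDTree(emb)
    # query enough neighbors to find one outside the Theiler window
    k = min(n_vec, 2 * theiler + 3)
    dist, nbr = tree.query(emb, k=k)
    pair = np.full(n_vec, -1, dtype=int)
    for j in range(1, k):
        ok = (pair < 0) & (np.abs(nbr[:, j] - np.arange(n_vec)) > theiler) \
             & (dist[:, j] > 0)
        pair[ok] = nbr[ok, j]
    valid = pair >= 0
    if not valid.any():
        raise ValueError("no valid neighbor pairs outside the Theiler window")

    i_idx = np.flatnonzero(valid)
    j_idx = pair[valid]
    curve = np.full(max_steps + 1, np.nan)
    for step in range(max_steps + 1):
        ok = (i_idx + step < n_vec) & (j_idx + step < n_vec)
        if ok.sum() < 10:
            break
        d = np.linalg.norm(emb[i_idx[ok] + step] - emb[j_idx[ok] + step], axis=1)
        d = d[d > 0]
        if d.size < 10:
            break
        curve[step] = np.mean(np.log(d))
    steps = np.arange(curve.size)
    mask = (steps >= lo) & (steps <= hi) & np.isfinite(curve)
    if mask.sum() < 2:
        raise ValueError("divergence curve too short for the requested fit range")
    slope = float(np.polyfit(steps[mask], curve[mask], 1)[0])
    return LLEResult(lle=slope, divergence_curve=curve, fit_range=(lo, hi),
                     embedding=embedding, theiler=int(theiler))


# ---------------------------------------------------------------------------
# Per-subject profile

def complexity_profile(ibi: Series, lv: Series,
                       entropy_params: EntropyParams = EntropyParams(),
                       fit_range: tuple = (1, 10)) -> ComplexityProfile:
    """Compute all seven indices for one subject.

    Both series are z-normalized first; the LV series drops its first
    element when paired with the (one-shorter) IBI series for
    cross-sample entropy.  Embedding parameters for the Lyapunov
    estimates are selected per series by AMI + FNN.
    """
    stats_ibi = summary_stats(ibi) if ibi.unit == "seconds" else None
    stats_lv = summary_stats(lv) if lv.unit == "liters" else None
    z_ibi = znormalize(ibi)
    z_lv = znormalize(lv)

    def _stage(fn, label, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            raise ValueError(f"[{label}] {exc}") from exc

    d_ibi = _stage(dfa, "DFA_IBI", z_ibi)
    d_lv = _stage(dfa, "DFA_LV", z_lv)
    se_ibi = _stage(sample_entropy, "SampEn_IBI", z_ibi, entropy_params)
    se_lv = _stage(sample_entropy, "SampEn_LV", z_lv, entropy_params)
    lle_ibi = _stage(largest_lyapunov, "LLE_IBI", z_ibi, fit_range=fit_range)
    lle_lv = _stage(largest_lyapunov, "LLE_LV", z_lv, fit_range=fit_range)
    nz_lv = z_lv.values[1:] if len(z_lv) == len(z_ibi) + 1 else z_lv.values
    n = min(len(z_ibi), nz_lv.size)
    xse = _stage(cross_sample_entropy, "CrossSampEn",
                 z_ibi.with_values(z_ibi.values[:n]),
                 z_lv.with_values(nz_lv[:n]), entropy_params)
    return ComplexityProfile(
        dfa_ibi=d_ibi.alpha, dfa_lv=d_lv.alpha,
        sampen_ibi=se_ibi, sampen_lv=se_lv,
        lle_ibi=lle_ibi.lle, lle_lv=lle_lv.lle,
        cross_sampen_ibi_lv=xse,
        mean_ibi=stats_ibi.mean if stats_ibi else np.nan,
        cv_ibi=stats_ibi.cv if stats_ibi else np.nan,
        mean_lv=stats_lv.mean if stats_lv else np.nan,
        cv_lv=stats_lv.cv if stats_lv else np.nan,
        params={
            "entropy_m": entropy_params.m, "entropy_r": entropy_params.r,
            "embedding_ibi": (lle_ibi.embedding.m, lle_ibi.embedding.tau),
            "embedding_lv": (lle_lv.embedding.m, lle_lv.embedding.tau),
            "cross_direction": "ibi_templates_in_lv",
            "dfa_r2_ibi": d_ibi.r_squared, "dfa_r2_lv": d_lv.r_squared,
        },
    )
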