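"""Synthetic respiratory signals and cohorts with known statistical structure.

Every generator is a pure function of its arguments including the seed, so
downstream stages (breath detection, complexity indices, classification) can
be tested against ground truth without any recorded data.

The breathing model: per-breath intervals and amplitudes are driven by
1/f^beta colored-noise processes with a prescribed mean, coefficient of
variation and inter-driver correlation, then rendered as half-sine breath
lobes split across ribcage/abdomen band channels.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    FEATURE_NAMES,
    BreathSpec,
    BreathTable,
    CohortDataset,
    CohortSpec,
    Series,
    Waveform,
)

# Fixed ribcage/abdomen mixing weights for the rendered waveform.
BAND_WEIGHTS = (0.6, 0.4)

# Drivers are clipped at +/-4 SD before the exponential link so that the
# highest coefficients of variation seen in uncontrolled non-atopic
# breathing (CV ~ 0.5) cannot produce non-positive intervals.
_DRIVER_CLIP = 4.0


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant sequence")
    return (x - x.mean()) / sd


def gen_colored_noise(n: int, beta: float, seed: int) -> Series:
    """Zero-mean, unit-SD noise with power spectral density ~ 1/f^beta.

    Built by frequency-domain synthesis: independent complex-Gaussian
    Fourier coefficients with amplitude f^(-beta/2), inverse-transformed and
    standardized.  beta=0 is white noise (DFA alpha ~ 0.5), beta=1 is 1/f
    noise (alpha ~ 1), beta=2 integrated white noise (alpha ~ 1.5); in
    general the expected DFA exponent is (beta + 1) / 2.
    """
    if n < 64:
        raise ValueError("n must be >= 64")
    if not np.isfinite(beta) or not (0 <= beta <= 3):
        raise ValueError("beta must be finite and within [0, 3]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coeffs = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = coeffs[-1].real
    x = np.fft.irfft(coeffs, n=n)
    return Series(_standardize(x), unit="dimensionless", index_kind="breath",
                  meta={"generator": "colored_noise", "beta": beta, "seed": seed})


def gen_logistic_series(n: int, r: float = 4.0, x0: float = 0.2,
                        burn_in: int = 100) -> Series:
    """Iterates of the logistic map x_{t+1} = r x_t (1 - x_t).

    At r=4 the map is chaotic with analytic Lyapunov exponent ln 2; at
    r < 3 the orbit converges to the fixed point 1 - 1/r.  Used as the
    calibration fixture for Lyapunov-exponent estimation.
    """
    if not (0 < x0 < 1):
        raise ValueError("x0 must lie in the open interval (0, 1)")
    if not (0 < r <= 4):
        raise ValueError("r must lie in (0, 4]")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    x = x0
    for _ in range(burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(n, dtype=float)
    for t in range(n):
        out[t] = x
        x = r * x * (1.0 - x)
    return Series(out, unit="dimensionless", index_kind="breath",
                  meta={"generator": "logistic", "r": r, "x0": x0, "burn_in": burn_in})


def gen_periodic_series(n: int, period: float, noise_sd: float = 0.0,
                        seed: int = 0) -> Series:
    """A unit-amplitude sinusoid of the given period plus iid Gaussian noise."""
    if period < 2:
        raise ValueError("period must be >= 2 samples")
    t = np.arange(n, dtype=float)
    x = np.sin(2.0 * np.pi * t / period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(n)
    return Series(x, unit="dimensionless", index_kind="breath",
                  meta={"generator": "periodic", "period": period,
                        "noise_sd": noise_sd, "seed": seed})


def gen_coupled_pair(n: int, coupling: float, seed: int = 0,
                     beta: float = 1.0) -> tuple[Series, Series]:
    """Two zero-mean unit-SD series whose fluctuation drivers correlate.

    coupling=1 returns elementwise-identical series; coupling=0 independent
    ones.  Fixture for cross-sample-entropy: stronger coupling means
    stronger synchronization, hence lower cross-SampEn.  The drivers are
    1/f^beta processes (default beta=1, breathing-like); beta=0 gives white
    drivers, for which cross-SampEn is insensitive to coupling because
    template matches are dominated by unaligned index pairs.
    """
    if abs(coupling) > 1:
        raise ValueError("|coupling| must be <= 1")
    rng = np.random.default_rng(seed)
    if beta == 0.0:
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
    else:
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        e1 = gen_colored_noise(n, beta, int(s1)).values
        e2 = gen_colored_noise(n, beta, int(s2)).values
    a = _standardize(e1)
    e2 = _standardize(e2)
    if coupling == 1.0:
        b = a.copy()
    elif coupling == -1.0:
        b = -a
    else:
        b = _standardize(coupling * a + math.sqrt(1.0 - coupling**2) * e2)
    meta = {"generator": "coupled_pair", "coupling": coupling, "seed": seed}
    return (Series(a, meta=dict(meta, channel="a")),
            Series(b, meta=dict(meta, channel="b")))


def _lognormal_link(driver: np.ndarray, mean: float, cv: float) -> np.ndarray:
    """Map a standardized driver to a positive sequence with given mean/CV.

    Uses the lognormal parameterization sigma^2 = ln(1 + cv^2) so the target
    mean and CV are hit exactly for a Gaussian driver; the driver is clipped
    at +/-4 SD first, which keeps extreme draws physiologic.
    """
    if cv == 0:
        return np.full(driver.shape, mean)
    d = np.clip(driver, -_DRIVER_CLIP, _DRIVER_CLIP)
    sigma = math.sqrt(math.log1p(cv * cv))
    return mean * np.exp(sigma * d - 0.5 * sigma * sigma)


def gen_breath_series(spec: BreathSpec) -> tuple[Series, Series]:
    """Breath-indexed IBI and LV series drawn directly from a BreathSpec.

    This is the waveform generator without the rendering step: the same
    interval/amplitude draws that gen_breath_waveform feeds to the renderer.
    Returns (ibi in seconds, lv in liters).
    """
    n = max(64, int(round(spec.duration / spec.mean_ibi)))
    rng = np.random.default_rng(spec.seed)
    s_ibi, s_lv, s_mix = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    u_ibi = gen_colored_noise(n, spec.beta_ibi, s_ibi).values
    e_lv = gen_colored_noise(n, spec.beta_lv, s_lv).values
    c = spec.coupling
    u_lv = c * u_ibi + math.sqrt(max(0.0, 1.0 - c * c)) * e_lv
    if abs(c) < 1.0:
        u_lv = _standardize(u_lv)
    elif c == -1.0:
        u_lv = -u_ibi
    else:
        u_lv = u_ibi.copy()
    ibi = _lognormal_link(u_ibi, spec.mean_ibi, spec.cv_ibi)
    lv = _lognormal_link(u_lv, spec.mean_lv, spec.cv_lv)
    # truncate to the requested recording duration
    keep = np.searchsorted(np.cumsum(ibi), spec.duration, side="right")
    keep = max(3, min(n, keep + 1))
    meta = {"generator": "breath_series", "spec_seed": spec.seed}
    return (Series(ibi[:keep], unit="seconds", meta=dict(meta, role="ibi")),
            Series(lv[:keep], unit="liters", meta=dict(meta, role="lv")))


def gen_breath_waveform(spec: BreathSpec, fs: float = 1000.0
                        ) -> tuple[Waveform, BreathTable]:
    """Render a two-band plethysmography waveform from a BreathSpec.

    Each breath k is a half-sine volume lobe peaking at amplitude A_k, with
    consecutive peaks separated by exactly the drawn interval T_k, so the
    ground-truth BreathTable's peak-to-peak differences equal the interval
    draws.  The lobe is split across ribcage/abdomen channels with 60/40
    mixing plus a small per-breath jitter in the split, and
    volume_ref = 0.6*ribcage + 0.4*abdomen exactly.
    """
    if fs < 10:
        raise ValueError("fs must be >= 10 Hz")
    ibi_s, lv_s = gen_breath_series(spec)
    intervals = ibi_s.values
    amplitudes = lv_s.values
    # peak k sits at t0 + sum of the first k intervals
    t0 = intervals[0] / 2.0
    peak_times = t0 + np.concatenate(([0.0], np.cumsum(intervals[:-1])))
    n_samples = int(round(fs * spec.duration))
    last = np.searchsorted(peak_times, (n_samples - 1) / fs - intervals[-1] / 2.0)
    peak_times = peak_times[:last]
    amplitudes = amplitudes[:last]
    if peak_times.size < 2:
        raise ValueError("duration too short to render at least 2 breaths")

    t = np.arange(n_samples) / fs
    volume = np.zeros(n_samples)
    rib = np.zeros(n_samples)
    abd = np.zeros(n_samples)
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31 - 1))
    split_jitter = 0.05 * rng.standard_normal(peak_times.size)
    w_r, w_a = BAND_WEIGHTS
    gaps = np.diff(peak_times)
    for k, (tk, ak) in enumerate(zip(peak_times, amplitudes)):
        g_left = gaps[k - 1] if k > 0 else intervals[0]
        g_right = gaps[k] if k < gaps.size else intervals[-1]
        lo = np.searchsorted(t, tk - g_left / 2.0)
        mid = np.searchsorted(t, tk)
        hi = np.searchsorted(t, tk + g_right / 2.0)
        lobe_l = ak * np.cos(np.pi * (t[lo:mid] - tk) / g_left)
        lobe_r = ak * np.cos(np.pi * (t[mid:hi] - tk) / g_right)
        lobe = np.concatenate([np.clip(lobe_l, 0.0, None), np.clip(lobe_r, 0.0, None)])
        frac = np.clip(w_r + split_jitter[k], 0.4, 0.8)
        volume[lo:hi] += lobe
        rib[lo:hi] += lobe * frac / w_r
        abd[lo:hi] += lobe * (1.0 - frac) / w_a
    wf = Waveform(fs=fs, ribcage=rib, abdomen=abd, volume_ref=volume,
                  duration=spec.duration)
    table = BreathTable(peak_times=peak_times, peak_volumes=amplitudes)
    return wf, table


# ---------------------------------------------------------------------------
# Cohorts

#: Synthetic per-group breathing specifications.  Mean/CV of the interval and
#: volume series follow the cohort summary statistics of the study design
#: (healthy / controlled atopic / uncontrolled atopic / uncontrolled
#: non-atopic); the spectral exponents, coupling and the implied complexity
#: ordering (healthy most fractal and chaotic, uncontrolled non-atopic least)
#: are synthetic choices, not measured group values.
DEFAULT_GROUP_SPECS: dict[str, BreathSpec] = {
    "Healthy": BreathSpec(mean_ibi=3.51, cv_ibi=0.13, mean_lv=0.64, cv_lv=0.27,
                          beta_ibi=1.0, beta_lv=1.0, coupling=0.1),
    "CAA": BreathSpec(mean_ibi=2.90, cv_ibi=0.22, mean_lv=0.66, cv_lv=0.61,
                      beta_ibi=0.7, beta_lv=0.7, coupling=0.3),
    "UAA": BreathSpec(mean_ibi=3.47, cv_ibi=0.26, mean_lv=0.76, cv_lv=0.63,
                      beta_ibi=0.4, beta_lv=0.5, coupling=0.6),
    "UNAA": BreathSpec(mean_ibi=4.03, cv_ibi=0.51, mean_lv=0.77, cv_lv=0.66,
                       beta_ibi=0.1, beta_lv=0.3, coupling=0.8),
}


def default_cohort_spec(n_per_group: int = 10, seed: int = 0,
                        duration: float = 3600.0) -> CohortSpec:
    """The 4 x n study design with the default synthetic group specs."""
    groups = []
    for label, spec in DEFAULT_GROUP_SPECS.items():
        groups.append((label, n_per_group,
                       BreathSpec(**{**spec.__dict__, "duration": duration})))
    return CohortSpec(groups=groups, seed=seed)


def gen_cohort(spec: CohortSpec, profiler=None) -> CohortDataset:
    """Simulate a labelled cohort and compute its feature matrix.

    Two modes per group, chosen by the third tuple element:

    * a ``BreathSpec`` — simulate breath-indexed IBI/LV series per subject
      and compute the seven complexity indices with ``profiler`` (defaults
      to :func:`respiro.complexity.complexity_profile`);
    * a ``{feature: (mean, sd)}`` table — draw features directly from
      independent Gaussians (fast path for classifier tests).
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels, ids = [], [], []
    for label, n_subj, desc in spec.groups:
        for i in range(n_subj):
            sid = f"{label}_{i:02d}"
            subj_seed = int(rng.integers(0, 2**31 - 1))
            if isinstance(desc, BreathSpec):
                if profiler is None:
                    from .complexity import complexity_profile
                    profiler = complexity_profile
                bs = BreathSpec(**{**desc.__dict__, "seed": subj_seed})
                ibi, lv = gen_breath_series(bs)
                prof = profiler(ibi, lv)
                row = {k: prof.as_row()[k] for k in FEATURE_NAMES}
            elif isinstance(desc, dict):
                row = {}
                for feat, (mu, sd) in desc.items():
                    row[feat] = mu + sd * rng.standard_normal()
            else:
                raise TypeError(
                    "group description must be a BreathSpec or a {feature: (mean, sd)} dict"
                )
            rows.append(row)
            labels.append(label)
            ids.append(sid)
    features = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    return CohortDataset(features, pd.Series(labels, index=features.index, name="group"))
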