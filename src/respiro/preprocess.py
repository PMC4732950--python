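"""From band waveforms to normalized breath-indexed series.

Stages: linear volume calibration of the two plethysmography bands, peak
detection, extraction of the inter-breath-interval (IBI) and lung-volume
(LV) series, artifact removal, and z-normalization.  Sample statistics use
the n-1 denominator throughout, so a z-normalized series has sample SD
exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .types import BreathTable, Series, Waveform


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    cv: float
    flags: tuple = ()


@dataclass(frozen=True)
class LinearCalibration:
    """Affine map (ribcage, abdomen) -> volume fitted by least squares.

    A deliberately simple stand-in for a nonlinear calibration stage: the
    synthetic waveforms are built from an affine band mix, and downstream
    complexity indices are invariant to the calibration's linearity.
    """

    w_ribcage: float
    w_abdomen: float
    intercept: float
    r_squared: float

    def predict(self, ribcage: np.ndarray, abdomen: np.ndarray) -> np.ndarray:
        return (self.w_ribcage * np.asarray(ribcage, float)
                + self.w_abdomen * np.asarray(abdomen, float) + self.intercept)


@dataclass(frozen=True)
class RemovalLog:
    removed_indices: tuple
    reasons: tuple
    warning: bool = False


def calibrate_volume(ribcage, abdomen, volume_ref
                     ) -> tuple[LinearCalibration, Series]:
    """Fit volume = w_r*ribcage + w_a*abdomen + c by ordinary least squares."""
    rib = np.asarray(ribcage, dtype=float)
    abd = np.asarray(abdomen, dtype=float)
    vol = np.asarray(volume_ref, dtype=float)
    if not (rib.size == abd.size == vol.size) or rib.size < 100:
        raise ValueError("inputs must have equal length >= 100")
    if np.ptp(vol) == 0:
        raise ValueError("volume_ref is constant; nothing to calibrate against")
    if np.ptp(rib) == 0 and np.ptp(abd) == 0:
        raise ValueError("both band signals are constant (rank-deficient)")
    X = np.column_stack([rib, abd, np.ones_like(rib)])
    coef, *_ = np.linalg.lstsq(X, vol, rcond=None)
    pred = X @ coef
    ss_res = float(np.sum((vol - pred) ** 2))
    ss_tot = float(np.sum((vol - vol.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    cal = LinearCalibration(w_ribcage=float(coef[0]), w_abdomen=float(coef[1]),
                            intercept=float(coef[2]), r_squared=r2)
    series = Series(pred, unit="liters", index_kind="time",
                    meta={"stage": "calibrate_volume", "r_squared": r2})
    return cal, series


def detect_breaths(volume: Series, fs: float, min_separation: float = 1.0,
                   min_prominence: float = 0.5) -> BreathTable:
    """Detect breath peaks in a time-indexed volume signal.

    ``min_separation`` is in seconds (default 1 s, below any physiologic
    inter-breath interval); ``min_prominence`` is a fraction of the signal
    SD (default 0.5).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = volume.values
    if x.size < 3:
        raise ValueError("signal too short for peak detection")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("no peaks found: signal is constant")
    distance = max(1, int(round(min_separation * fs)))
    idx, _ = find_peaks(x, distance=distance, prominence=min_prominence * sd)
    if idx.size == 0:
        raise ValueError("no peaks found")
    return BreathTable(peak_times=idx / fs, peak_volumes=x[idx])


def series_from_breaths(breaths: BreathTable) -> tuple[Series, Series]:
    """IBI (peak-to-peak differences, length n-1) and LV (peak amplitudes, n)."""
    if len(breaths) < 2:
        raise ValueError("need at least 2 peaks to form an IBI series")
    ibi = np.diff(breaths.peak_times)
    lv = breaths.peak_volumes.copy()
    return (Series(ibi, unit="seconds", index_kind="breath",
                   meta={"stage": "series_from_breaths"}),
            Series(lv, unit="liters", index_kind="breath",
                   meta={"stage": "series_from_breaths"}))


def remove_artifacts(series: Series, ibi_bounds: tuple = (0.5, 15.0),
                     z_limit: float = 5.0) -> tuple[Series, RemovalLog]:
    """Drop physiologically implausible or outlying values.

    Bounds are applied first (for interval series, default 0.5-15 s), then a
    robust z-rule: values more than ``z_limit`` robust SDs (1.4826*MAD) from
    the median are dropped.  A warning flag is set when more than 20% of the
    series is removed.
    """
    x = series.values
    n = x.size
    removed: list[int] = []
    reasons: list[str] = []
    keep = np.ones(n, dtype=bool)
    if series.unit == "seconds" and ibi_bounds is not None:
        lo, hi = ibi_bounds
        bad = (x < lo) | (x > hi)
        for i in np.flatnonzero(bad):
            removed.append(int(i))
            reasons.append("bounds")
        keep &= ~bad
    if z_limit is not None and keep.sum() >= 2:
        med = np.median(x[keep])
        mad = np.median(np.abs(x[keep] - med))
        robust_sd = 1.4826 * mad
        if robust_sd > 0:
            bad = keep & (np.abs(x - med) > z_limit * robust_sd)
            for i in np.flatnonzero(bad):
                removed.append(int(i))
                reasons.append("z")
            keep &= ~bad
    frac = len(removed) / n if n else 0.0
    warn = frac > 0.20
    if warn:
        warnings.warn(f"remove_artifacts dropped {frac:.0%} of the series",
                      stacklevel=2)
    if keep.sum() == 0:
        raise ValueError("artifact removal emptied the series")
    cleaned = series.with_values(x[keep])
    order = np.argsort(removed) if removed else []
    log = RemovalLog(removed_indices=tuple(removed[i] for i in order),
                     reasons=tuple(reasons[i] for i in order), warning=warn)
    return cleaned, log


def znormalize(series: Series) -> Series:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = series.values
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series cannot be z-normalized")
    z = (x - x.mean()) / sd
    return Series(z, unit="dimensionless", index_kind=series.index_kind,
                  meta=dict(series.meta, normalized=True,
                            orig_unit=series.unit))


def summary_stats(series: Series) -> SummaryStats:
    """Mean and coefficient of variation (sample SD / mean)."""
    x = series.values
    if x.size < 2:
        raise ValueError("need at least 2 values for summary statistics")
    mean = float(x.mean())
    if mean == 0:
        return SummaryStats(mean=0.0, cv=float("nan"), flags=("cv_undefined",))
    return SummaryStats(mean=mean, cv=float(x.std(ddof=1) / mean))
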