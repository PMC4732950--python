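"""Core data containers for breath-by-breath respiratory analysis.

The pipeline works on two kinds of per-subject sequences: the inter-breath
interval (IBI) series, in seconds, and the lung-volume (LV) series, in
liters — both indexed by breath number — plus the raw two-band
plethysmography waveforms they are extracted from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

VALID_UNITS = ("seconds", "liters", "dimensionless")
VALID_INDEX_KINDS = ("breath", "time")

#: Canonical order of the seven per-subject complexity indices.
FEATURE_NAMES = (
    "DFA_IBI",
    "DFA_LV",
    "SampEn_IBI",
    "SampEn_LV",
    "LLE_IBI",
    "LLE_LV",
    "CrossSampEn_IBI_LV",
)

GROUP_LABELS = ("Healthy", "CAA", "UAA", "UNAA")


@dataclass(frozen=True)
class Series:
    """An ordered real-valued sequence with unit and index bookkeeping.

    IBI series carry unit ``seconds`` and must be strictly positive;
    z-normalized series are ``dimensionless``.
    """

    values: np.ndarray
    unit: str = "dimensionless"
    index_kind: str = "breath"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("Series requires a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("Series values must all be finite")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.index_kind not in VALID_INDEX_KINDS:
            raise ValueError(
                f"index_kind must be one of {VALID_INDEX_KINDS}, got {self.index_kind!r}"
            )
        if self.unit == "seconds" and np.any(vals <= 0):
            raise ValueError("IBI series (unit='seconds') must be strictly positive")

    def __len__(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray, **changes) -> "Series":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class Waveform:
    """Two-band plethysmography record sampled at ``fs`` Hz."""

    fs: float
    ribcage: np.ndarray
    abdomen: np.ndarray
    duration: float
    volume_ref: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        n = int(round(self.fs * self.duration))
        for name in ("ribcage", "abdomen", "volume_ref"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size != n:
                raise ValueError(
                    f"{name} length {arr.size} != round(fs*duration) = {n}"
                )


@dataclass(frozen=True)
class BreathTable:
    """Per-breath peak times (s) and peak amplitudes (L)."""

    peak_times: np.ndarray
    peak_volumes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        v = np.asarray(self.peak_volumes, dtype=float)
        object.__setattr__(self, "peak_times", t)
        object.__setattr__(self, "peak_volumes", v)
        if t.size != v.size:
            raise ValueError("peak_times and peak_volumes must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("peak_times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("peak_volumes must be positive")

    def __len__(self) -> int:
        return int(self.peak_times.size)


@dataclass(frozen=True)
class BreathSpec:
    """Statistical description of one subject's spontaneous breathing.

    ``beta_ibi``/``beta_lv`` are the spectral exponents of the 1/f^beta
    fluctuation drivers (beta=1 for healthy-like long-range correlation,
    beta=0 for uncorrelated breathing); ``coupling`` is the correlation
    between the IBI and LV drivers.
    """

    mean_ibi: float = 3.51
    cv_ibi: float = 0.13
    mean_lv: float = 0.64
    cv_lv: float = 0.27
    beta_ibi: float = 1.0
    beta_lv: float = 1.0
    coupling: float = 0.3
    duration: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_ibi <= 0 or self.mean_lv <= 0:
            raise ValueError("mean_ibi and mean_lv must be positive")
        if self.cv_ibi < 0 or self.cv_lv < 0:
            raise ValueError("cv values must be >= 0")
        if abs(self.coupling) > 1:
            raise ValueError("|coupling| must be <= 1")
        if self.duration < 3 * self.mean_ibi:
            raise ValueError("duration must cover at least 3 mean breaths")


@dataclass(frozen=True)
class CohortSpec:
    """Groups of subjects, each described by a BreathSpec or a feature table.

    ``groups`` maps label -> (n_subjects, BreathSpec) for simulation mode, or
    label -> (n_subjects, {feature: (mean, sd)}) for direct feature draws.
    """

    groups: list
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be unique")
        if not self.groups:
            raise ValueError("CohortSpec requires at least one group")
        for label, n, _ in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have n_subjects >= 1")


@dataclass(frozen=True)
class ComplexityProfile:
    """The seven nonlinear indices for one subject, plus series summaries."""

    dfa_ibi: float
    dfa_lv: float
    sampen_ibi: float
    sampen_lv: float
    lle_ibi: float
    lle_lv: float
    cross_sampen_ibi_lv: float
    mean_ibi: float = np.nan
    cv_ibi: float = np.nan
    mean_lv: float = np.nan
    cv_lv: float = np.nan
    params: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "DFA_IBI": self.dfa_ibi,
            "DFA_LV": self.dfa_lv,
            "SampEn_IBI": self.sampen_ibi,
            "SampEn_LV": self.sampen_lv,
            "LLE_IBI": self.lle_ibi,
            "LLE_LV": self.lle_lv,
            "CrossSampEn_IBI_LV": self.cross_sampen_ibi_lv,
            "mean_IBI": self.mean_ibi,
            "CV_IBI": self.cv_ibi,
            "mean_LV": self.mean_lv,
            "CV_LV": self.cv_lv,
        }


class CohortDataset:
    """Subjects x features matrix with group labels.

    Thin wrapper over a pandas DataFrame whose index is subject_id, whose
    columns are feature names, plus a parallel ``labels`` Series.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.Series):
        if not features.index.equals(labels.index):
            raise ValueError("features and labels must share the same subject index")
        if features.isna().any().any():
            raise ValueError("CohortDataset features contain missing values")
        self.features = features
        self.labels = labels.astype(str)

    @property
    def feature_names(self) -> list:
        return list(self.features.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.features.index)

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def classes(self) -> list:
        return sorted(self.labels.unique())

    def relabel(self, label_map: dict) -> "CohortDataset":
        """Regroup labels, e.g. collapsing asthma subtypes into one class."""
        new = self.labels.map(lambda g: label_map.get(g, g))
        return CohortDataset(self.features.copy(), new)

    def select(self, feature_names: list) -> "CohortDataset":
        missing = [f for f in feature_names if f not in self.features.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return CohortDataset(self.features[list(feature_names)].copy(), self.labels)

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.features.copy()
        tidy.insert(0, "group", self.labels)
        tidy = tidy.reset_index(names="subject_id")
        return tidy.melt(
            id_vars=["subject_id", "group"], var_name="feature", value_name="value"
        )

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "CohortDataset":
        wide = tidy.pivot(index="subject_id", columns="feature", values="value")
        labels = tidy.drop_duplicates("subject_id").set_index("subject_id")["group"]
        return cls(wide, labels.loc[wide.index])
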