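"""CSV dialects for series, waveforms, breath tables and cohorts.

All files are plain CSV.  Series: two columns (index, value) with unit and
index kind in a ``# key: value`` comment header.  Waveform: columns
(ribcage, abdomen[, volume_ref]) with fs/duration in the header.
BreathTable: (peak_time_s, peak_volume_L).  Cohort: tidy
(subject_id, group, feature, value).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BreathTable, CohortDataset, Series, Waveform


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path: Path) -> tuple[dict, int]:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            skip += 1
    return meta, skip


def write_series(series: Series, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {"unit": series.unit, "index_kind": series.index_kind})
        fh.write("index,value\n")
        for i, v in enumerate(series.values):
            fh.write(f"{i},{float(v)!r}\n")


def read_series(path) -> Series:
    path = Path(path)
    meta, skip = _read_header(path)
    values = []
    with open(path) as fh:
        for _ in range(skip):
            next(fh)
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=skip + 2):
            if not row:
                continue
            try:
                values.append(float(row[1]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty series")
    return Series(np.asarray(values), unit=meta.get("unit", "dimensionless"),
                  index_kind=meta.get("index_kind", "breath"))


def write_waveform(wf: Waveform, path) -> None:
    path = Path(path)
    cols = {"ribcage": wf.ribcage, "abdomen": wf.abdomen}
    if wf.volume_ref is not None:
        cols["volume_ref"] = wf.volume_ref
    with open(path, "w") as fh:
        _write_header(fh, {"fs": wf.fs, "duration": wf.duration})
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_waveform(path) -> Waveform:
    path = Path(path)
    meta, skip = _read_header(path)
    if "fs" not in meta:
        raise ValueError(f"{path}: missing '# fs:' header")
    df = pd.read_csv(path, skiprows=skip)
    fs = float(meta["fs"])
    duration = float(meta.get("duration", len(df) / fs))
    return Waveform(fs=fs, ribcage=df["ribcage"].to_numpy(),
                    abdomen=df["abdomen"].to_numpy(),
                    volume_ref=(df["volume_ref"].to_numpy()
                                if "volume_ref" in df else None),
                    duration=duration)


def write_breath_table(table: BreathTable, path) -> None:
    pd.DataFrame({"peak_time_s": table.peak_times,
                  "peak_volume_L": table.peak_volumes}).to_csv(path, index=False)


def read_breath_table(path) -> BreathTable:
    df = pd.read_csv(path)
    return BreathTable(peak_times=df["peak_time_s"].to_numpy(),
                       peak_volumes=df["peak_volume_L"].to_numpy())


def write_cohort(data: CohortDataset, path) -> None:
    data.to_tidy().to_csv(path, index=False)


def read_cohort(path) -> CohortDataset:
    tidy = pd.read_csv(path)
    required = {"subject_id", "group", "feature", "value"}
    if not required.issubset(tidy.columns):
        raise ValueError(f"{path}: cohort CSV needs columns {sorted(required)}")
    return CohortDataset.from_tidy(tidy)
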