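"""CSV/JSON readers and writers for recordings, ground truth and reports.

Column conventions (µM for concentrations, detector units for intensities):

* concentrations: ``time_s,hbo2_short,hhb_short,hbo2_long,hhb_long``
* intensities:    ``time_s,i760_short,i850_short,i760_long,i850_long``
* ground truth:   ``time_s,hbo2_evoked,hhb_evoked``

Readers validate column presence and uniform, monotone time stamps and
infer the sampling rate from the time column.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .series import SampledSeries
from .synth import ConcentrationRecording, GroundTruth, IntensityRecording

__all__ = [
    "CONCENTRATION_COLUMNS",
    "INTENSITY_COLUMNS",
    "write_concentrations",
    "read_concentrations",
    "write_intensities",
    "read_intensities",
    "write_ground_truth",
    "write_json",
]

CONCENTRATION_COLUMNS = ["hbo2_short", "hhb_short", "hbo2_long", "hhb_long"]
INTENSITY_COLUMNS = ["i760_short", "i850_short", "i760_long", "i850_long"]


def _frame(time_s: np.ndarray, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame({"time_s": time_s, **columns})


def write_concentrations(rec: ConcentrationRecording, path: str | Path) -> None:
    df = _frame(
        rec.hbo2_short.times(),
        {name: getattr(rec, name).values for name in CONCENTRATION_COLUMNS},
    )
    df.to_csv(path, index=False)


def write_intensities(rec: IntensityRecording, path: str | Path) -> None:
    df = _frame(
        rec.i760_short.times(),
        {name: getattr(rec, name).values for name in INTENSITY_COLUMNS},
    )
    df.to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    df = _frame(
        truth.hbo2_evoked.times(),
        {"hbo2_evoked": truth.hbo2_evoked.values, "hhb_evoked": truth.hhb_evoked.values},
    )
    df.to_csv(path, index=False)


def _read_table(path: str | Path, columns: list[str]) -> tuple[float, pd.DataFrame]:
    df = pd.read_csv(path)
    missing = [c for c in ["time_s", *columns] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: time stamps are not uniformly spaced")
    return 1.0 / dt.mean(), df


def read_concentrations(path: str | Path, baseline_duration_s: float) -> ConcentrationRecording:
    fs, df = _read_table(path, CONCENTRATION_COLUMNS)
    series = {
        name: SampledSeries(df[name].to_numpy(dtype=float), fs)
        for name in CONCENTRATION_COLUMNS
    }
    return ConcentrationRecording(baseline_duration_s=baseline_duration_s, **series)


def read_intensities(path: str | Path, baseline_duration_s: float) -> IntensityRecording:
    fs, df = _read_table(path, INTENSITY_COLUMNS)
    series = {
        name: SampledSeries(df[name].to_numpy(dtype=float), fs)
        for name in INTENSITY_COLUMNS
    }
    return IntensityRecording(baseline_duration_s=baseline_duration_s, **series)


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
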