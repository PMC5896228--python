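"""Uniformly sampled time series — the common currency of the pipeline.

Every signal in the package (light intensity, optical density, chromophore
concentration, filtered output) is a :class:`SampledSeries`: a finite real
array with a sampling rate and a start time. Operations that combine two
series require equal rates; most also require equal lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledSeries"]


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Sample values. Stored as a float64 numpy array; must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (n samples / fs)."""
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray) -> "SampledSeries":
        """A new series with the same clock but different samples."""
        return SampledSeries(values, self.fs, self.t0)

    def slice_seconds(self, start_s: float, stop_s: float | None = None) -> "SampledSeries":
        """Sub-series between two times (relative to t0, stop exclusive)."""
        i0 = int(round(start_s * self.fs))
        i1 = len(self) if stop_s is None else int(round(stop_s * self.fs))
        if not (0 <= i0 <= i1 <= len(self)):
            raise ValueError(
                f"span [{start_s}, {stop_s}) s outside record of {self.duration_s} s"
            )
        return SampledSeries(self.values[i0:i1], self.fs, self.t0 + i0 / self.fs)

    def same_clock(self, other: "SampledSeries") -> bool:
        return len(self) == len(other) and self.fs == other.fs
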