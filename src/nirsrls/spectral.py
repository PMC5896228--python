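"""Block averaging, PSD and the band-energy contrast-to-noise ratio.

A block-design evoked response concentrates its power at the stimulation
fundamental (0.025 Hz for a 20 s/20 s paradigm) and its harmonics. The CNR
statistic integrates the one-sided power spectral density over narrow
"signal" bands around the fundamental and second harmonic and over a broad
"noise" range (0-5 Hz minus the signal bands), and reports

    CNR% = 100 * sqrt(E_signal / E_noise).

The PSD is a single Hann-windowed periodogram of 4000 task-period samples,
not a Welch average: the signal bands are only 0.012 Hz wide, so the full
fs/4000 = 0.0025 Hz resolution is needed. The mean is removed before
windowing and the DC bin is excluded from both energies (a baseline offset
is not interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .design import BlockDesign
from .series import SampledSeries

__all__ = ["BandSet", "CNRReport", "block_average", "psd", "cnr", "correlation"]


@dataclass(frozen=True)
class BandSet:
    """Signal frequency bands and the upper edge of the noise range.

    Defaults are the fundamental band 0.019-0.031 Hz and second-harmonic
    band 0.044-0.056 Hz of the 0.025 Hz paradigm, with noise taken over the
    rest of (0, 5] Hz.
    """

    signal_bands: tuple[tuple[float, float], ...] = ((0.019, 0.031), (0.044, 0.056))
    noise_upper_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_upper_hz <= 0:
            raise ValueError("noise_upper_hz must be > 0")
        bands = sorted(self.signal_bands)
        for lo, hi in bands:
            if not (0 < lo < hi <= self.noise_upper_hz):
                raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi <= noise_upper_hz")
        for (_, hi1), (lo2, _) in zip(bands, bands[1:]):
            if hi1 > lo2:
                raise ValueError("signal bands must be disjoint")

    @classmethod
    def from_design(cls, design: BlockDesign, half_width_hz: float = 0.006,
                    noise_upper_hz: float = 5.0) -> "BandSet":
        """Bands centred on the paradigm fundamental and second harmonic."""
        f1, f2 = design.harmonic_hz(1), design.harmonic_hz(2)
        return cls(
            signal_bands=((f1 - half_width_hz, f1 + half_width_hz),
                          (f2 - half_width_hz, f2 + half_width_hz)),
            noise_upper_hz=noise_upper_hz,
        )

    def in_signal(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask: bin centre inside a closed signal band."""
        mask = np.zeros(freqs.shape, dtype=bool)
        for lo, hi in self.signal_bands:
            mask |= (freqs >= lo) & (freqs <= hi)
        return mask


@dataclass(frozen=True)
class CNRReport:
    """Band-integrated energies and the percent CNR statistic."""

    signal_energy: float
    noise_energy: float
    cnr_percent: float
    n_points_used: int

    def to_dict(self) -> dict:
        return {
            "signal_energy": self.signal_energy,
            "noise_energy": self.noise_energy,
            "cnr_percent": self.cnr_percent,
            "n_points_used": self.n_points_used,
        }


def block_average(
    series: SampledSeries, design: BlockDesign, pre_stim_s: float = 2.0
) -> SampledSeries:
    """Average the task epochs of a record into one stim+rest epoch.

    Epochs start at each stimulus onset (baseline excluded). Each epoch is
    re-baselined by subtracting the mean of the ``pre_stim_s`` seconds
    immediately preceding its onset (clipped to the available record), then
    the epochs are averaged elementwise.
    """
    fs = series.fs
    i0 = int(round(design.baseline_duration_s * fs))
    epoch_len = int(round(design.block_duration_s * fs))
    needed = i0 + design.n_blocks * epoch_len
    if len(series) < needed:
        raise ValueError(
            f"record has {len(series)} samples, needs {needed} for "
            f"{design.n_blocks} blocks after the baseline"
        )
    pre_n = int(round(pre_stim_s * fs))
    x = series.values
    epochs = []
    for k in range(design.n_blocks):
        start = i0 + k * epoch_len
        pre = x[max(0, start - pre_n) : start]
        offset = pre.mean() if pre.size else 0.0
        epochs.append(x[start : start + epoch_len] - offset)
    return SampledSeries(np.mean(epochs, axis=0), fs)


def psd(series: SampledSeries, n_points: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram of the first ``n_points`` samples.

    Density-scaled: summing power * df recovers the (mean-removed, windowed)
    signal variance. Frequency resolution is fs/n_points. The record must
    contain at least n_points samples — no zero padding.
    """
    if len(series) < n_points:
        raise ValueError(
            f"record has {len(series)} samples, PSD needs {n_points} (no padding)"
        )
    freqs, power = sps.periodogram(
        series.values[:n_points],
        fs=series.fs,
        window="hann",
        detrend="constant",
        scaling="density",
    )
    return freqs, power


def cnr(freqs: np.ndarray, power: np.ndarray, bands: BandSet = BandSet()) -> CNRReport:
    """Band-energy contrast-to-noise ratio from a one-sided PSD.

    signal_energy integrates power*df over bins whose centre falls in a
    closed signal band; noise_energy over (0, noise_upper_hz] excluding the
    signal bands and the DC bin. cnr_percent = 100*sqrt(Es/En).
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.shape != power.shape:
        raise ValueError("freqs and power must have the same shape")
    if freqs[-1] < bands.noise_upper_hz - 1e-12:
        raise ValueError(
            f"PSD extends to {freqs[-1]} Hz, below the noise range upper edge "
            f"{bands.noise_upper_hz} Hz"
        )
    df = freqs[1] - freqs[0]
    in_range = (freqs > 0) & (freqs <= bands.noise_upper_hz)
    sig_mask = bands.in_signal(freqs) & in_range
    noise_mask = in_range & ~sig_mask
    signal_energy = float(np.sum(power[sig_mask]) * df)
    noise_energy = float(np.sum(power[noise_mask]) * df)
    if noise_energy == 0:
        raise ValueError("noise-band energy is zero: CNR undefined")
    return CNRReport(
        signal_energy=signal_energy,
        noise_energy=noise_energy,
        cnr_percent=100.0 * float(np.sqrt(signal_energy / noise_energy)),
        n_points_used=2 * (freqs.size - 1),
    )


def correlation(a: SampledSeries, b: SampledSeries, span_s: float) -> float:
    """Pearson correlation of two series over their first ``span_s`` seconds."""
    if a.fs != b.fs:
        raise ValueError("series must share a sampling rate")
    n = int(round(span_s * a.fs))
    if n < 2 or n > len(a) or n > len(b):
        raise ValueError(f"span {span_s} s invalid for records of {len(a)}/{len(b)} samples")
    xa, xb = a.values[:n], b.values[:n]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(xa, xb).statistic)
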