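"""Synthetic dual-channel fNIRS recordings with known ground truth.

The generator emulates a two-distance continuous-wave fNIRS measurement over
the auditory cortex during a block-design run: a short-separation channel
(13 mm) that samples superficial tissue only, and a long-separation channel
(35 mm) that additionally samples cortex. Systemic physiological
interference — cardiac pulsation, respiration and Mayer waves — is realized
once per recording and shared between the two channels; the evoked
hemodynamic response appears only in the long channel, attenuated by the
partial volume effect. Independent white sensor noise decorrelates the two
channels; with the default parameters the baseline cross-channel Pearson
correlation of the HbO2 series is ~0.89.

Amplitude calibration of the defaults
-------------------------------------
With unit coupling the expected baseline correlation is v/(v + sigma^2),
where v is the variance of the shared interference and sigma the white-noise
standard deviation. The default interference amplitudes (0.30, 0.15,
0.20 µM) give v ≈ 0.0766 µM²; noise_sd = 0.097 µM then yields r ≈ 0.890.
These constants were fixed analytically from that relation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .design import BlockDesign
from .series import SampledSeries

__all__ = [
    "InterferenceModel",
    "EvokedResponse",
    "GroundTruth",
    "ConcentrationRecording",
    "IntensityRecording",
    "boxcar_stimulus",
    "evoked_waveform",
    "generate_recording",
    "forward_intensities",
]


@dataclass(frozen=True)
class InterferenceModel:
    """Systemic physiological interference shared between channels.

    Amplitudes are HbO2 concentration amplitudes in µM; the HHb interference
    is the same realization divided by ``hbo2_hhb_interference_ratio``
    (physiological oscillations are predominantly an HbO2 phenomenon).
    Each oscillator has per-sample Gaussian frequency jitter (relative sd
    ``freq_jitter_sd``) and slow 10% amplitude modulation, so the
    interference is non-stationary and an adaptive filter must track it.
    """

    cardiac_freq_hz: float = 1.2
    cardiac_amp: float = 0.30
    resp_freq_hz: float = 0.25
    resp_amp: float = 0.15
    mayer_freq_hz: float = 0.10
    mayer_amp: float = 0.20
    freq_jitter_sd: float = 0.02
    coupling: float = 1.0
    noise_sd: float = 0.097
    hbo2_hhb_interference_ratio: float = 3.0

    def __post_init__(self) -> None:
        for name in ("cardiac_freq_hz", "resp_freq_hz", "mayer_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cardiac_amp", "resp_amp", "mayer_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coupling <= 0:
            raise ValueError("coupling must be > 0")
        if self.freq_jitter_sd < 0:
            raise ValueError("freq_jitter_sd must be >= 0")
        if self.hbo2_hhb_interference_ratio <= 1:
            raise ValueError("hbo2_hhb_interference_ratio must be > 1")

    def components(self) -> list[tuple[float, float]]:
        """(frequency Hz, amplitude µM) pairs of the three oscillators."""
        return [
            (self.cardiac_freq_hz, self.cardiac_amp),
            (self.resp_freq_hz, self.resp_amp),
            (self.mayer_freq_hz, self.mayer_amp),
        ]


@dataclass(frozen=True)
class EvokedResponse:
    """Shape and size of the cortical evoked response.

    Amplitudes are cortical-scale concentration changes in µM, i.e. before
    partial-volume attenuation; the long channel sees amplitude/pvef. HHb
    moves opposite to HbO2 and with smaller magnitude. The response onset
    lags the stimulus by ``onset_delay_s`` and the return to baseline lags
    the stimulus offset by ``recovery_delay_s``; both transitions are
    first-order exponentials.
    """

    hbo2_amp: float = 7.0
    hhb_amp: float = -2.3
    onset_delay_s: float = 4.0
    recovery_delay_s: float = 6.0
    rise_tau_s: float = 5.0
    fall_tau_s: float = 5.0

    def __post_init__(self) -> None:
        if self.hbo2_amp != 0 or self.hhb_amp != 0:
            if abs(self.hhb_amp) >= abs(self.hbo2_amp):
                raise ValueError("|hhb_amp| must be < hbo2_amp")
            if self.hbo2_amp * self.hhb_amp > 0:
                raise ValueError("hhb_amp must have sign opposite to hbo2_amp")
        if self.onset_delay_s < 0 or self.recovery_delay_s < 0:
            raise ValueError("delays must be >= 0")
        if self.rise_tau_s <= 0 or self.fall_tau_s <= 0:
            raise ValueError("time constants must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, for recovery tests.

    ``hbo2_evoked``/``hhb_evoked`` are at cortical scale (pre-partial-volume);
    the long channel contains these divided by the partial volume factor.
    """

    hbo2_evoked: SampledSeries
    hhb_evoked: SampledSeries
    stimulus_onsets: list[float]


@dataclass(frozen=True)
class ConcentrationRecording:
    """Dual-channel chromophore concentration changes (µM)."""

    hbo2_short: SampledSeries
    hhb_short: SampledSeries
    hbo2_long: SampledSeries
    hhb_long: SampledSeries
    baseline_duration_s: float

    def __post_init__(self) -> None:
        ref = self.hbo2_short
        for name in ("hhb_short", "hbo2_long", "hhb_long"):
            if not ref.same_clock(getattr(self, name)):
                raise ValueError(f"{name} does not share the recording clock")

    @property
    def fs(self) -> float:
        return self.hbo2_short.fs


@dataclass(frozen=True)
class IntensityRecording:
    """Dual-wavelength detected light intensities (detector units)."""

    i760_short: SampledSeries
    i850_short: SampledSeries
    i760_long: SampledSeries
    i850_long: SampledSeries
    baseline_duration_s: float

    @property
    def fs(self) -> float:
        return self.i760_short.fs


def boxcar_stimulus(design: BlockDesign, fs: float) -> SampledSeries:
    """0/1 stimulus indicator: baseline zeros, then n_blocks of stim/rest.

    Length is (baseline + n_blocks*(stim+rest)) * fs samples.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be > 0, got {fs}")
    n_base = int(round(design.baseline_duration_s * fs))
    n_stim = int(round(design.stim_duration_s * fs))
    n_rest = int(round(design.rest_duration_s * fs))
    block = np.concatenate([np.ones(n_stim), np.zeros(n_rest)])
    values = np.concatenate([np.zeros(n_base), np.tile(block, design.n_blocks)])
    return SampledSeries(values, fs)


def evoked_waveform(
    stimulus: SampledSeries, resp: EvokedResponse
) -> tuple[SampledSeries, SampledSeries]:
    """Evoked HbO2/HHb concentration waveforms driven by a 0/1 stimulus.

    The response follows a first-order relaxation toward a delayed drive:
    the drive turns on ``onset_delay_s`` after each stimulus onset and off
    ``recovery_delay_s`` after each offset; the state relaxes toward the
    drive with time constant ``rise_tau_s`` (rising) or ``fall_tau_s``
    (falling). HHb is the HbO2 shape scaled by hhb_amp/hbo2_amp.
    """
    u = stimulus.values
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("stimulus must be a 0/1 series")
    fs = stimulus.fs
    d_on = int(round(resp.onset_delay_s * fs))
    d_off = int(round(resp.recovery_delay_s * fs))
    # effective drive: union of [onset+d_on, offset+d_off) for each epoch
    on = np.flatnonzero(np.diff(np.concatenate([[0.0], u])) == 1)
    off = np.flatnonzero(np.diff(np.concatenate([u, [0.0]])) == -1) + 1
    g = np.zeros_like(u)
    for i0, i1 in zip(on, off):
        g[min(i0 + d_on, len(g)) : min(i1 + d_off, len(g))] = 1.0

    a_rise = np.exp(-1.0 / (resp.rise_tau_s * fs))
    a_fall = np.exp(-1.0 / (resp.fall_tau_s * fs))
    y = np.empty_like(g)
    state = 0.0
    for n in range(len(g)):
        a = a_rise if g[n] > state else a_fall
        state = g[n] + (state - g[n]) * a
        y[n] = state
    hbo2 = stimulus.with_values(resp.hbo2_amp * y)
    hhb = stimulus.with_values(resp.hhb_amp * y)
    return hbo2, hhb


def _oscillator_bank(
    interference: InterferenceModel, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """One realization of the summed interference oscillators (HbO2 scale).

    Each component is a sinusoid whose instantaneous frequency carries
    per-sample Gaussian jitter (phase random walk) and whose amplitude is
    modulated by 1 + 0.1*sin(2*pi*0.01 Hz*t + psi).
    """
    t = np.arange(n) / fs
    total = np.zeros(n)
    for f, amp in interference.components():
        if amp == 0:
            continue
        f_inst = f * (1.0 + interference.freq_jitter_sd * rng.standard_normal(n))
        phase = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.concatenate(
            [[0.0], np.cumsum(f_inst[:-1]) / fs]
        )
        am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
        total += amp * am * np.sin(phase)
    return total


def generate_recording(
    design: BlockDesign,
    interference: InterferenceModel,
    resp: EvokedResponse,
    fs: float = 10.0,
    pvef: float = 9.15,
    seed: int | None = None,
) -> tuple[ConcentrationRecording, GroundTruth]:
    """Generate a dual-channel concentration recording plus its ground truth.

    Per chromophore: short channel = shared interference + white noise;
    long channel = coupling * (same interference realization) + evoked/pvef
    + independent white noise. HHb interference is the HbO2 realization
    divided by ``hbo2_hhb_interference_ratio``. The same seed reproduces the
    recording bit for bit; a seed is mandatory.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic runs must be reproducible")
    if fs <= 0:
        raise ValueError(f"sampling rate must be > 0, got {fs}")
    if pvef <= 0:
        raise ValueError(f"pvef must be > 0, got {pvef}")
    nyquist = fs / 2
    for f, _ in interference.components():
        if f >= nyquist:
            raise ValueError(f"interference frequency {f} Hz >= Nyquist {nyquist} Hz")

    rng = np.random.default_rng(seed)
    stim = boxcar_stimulus(design, fs)
    n = len(stim)
    hbo2_ev, hhb_ev = evoked_waveform(stim, resp)

    shared = _oscillator_bank(interference, n, fs, rng)
    ratio = interference.hbo2_hhb_interference_ratio
    sd = interference.noise_sd
    c = interference.coupling

    hbo2_short = shared + sd * rng.standard_normal(n)
    hhb_short = shared / ratio + sd * rng.standard_normal(n)
    hbo2_long = c * shared + hbo2_ev.values / pvef + sd * rng.standard_normal(n)
    hhb_long = c * shared / ratio + hhb_ev.values / pvef + sd * rng.standard_normal(n)

    rec = ConcentrationRecording(
        hbo2_short=stim.with_values(hbo2_short),
        hhb_short=stim.with_values(hhb_short),
        hbo2_long=stim.with_values(hbo2_long),
        hhb_long=stim.with_values(hhb_long),
        baseline_duration_s=design.baseline_duration_s,
    )
    onsets = [
        design.baseline_duration_s + k * design.block_duration_s
        for k in range(design.n_blocks)
    ]
    truth = GroundTruth(hbo2_evoked=hbo2_ev, hhb_evoked=hhb_ev, stimulus_onsets=onsets)
    return rec, truth


def forward_intensities(
    rec: ConcentrationRecording,
    params_short,
    params_long,
    i0: float = 1.0,
) -> IntensityRecording:
    """Forward-model detected intensities from concentration changes.

    Applies the differential Beer-Lambert relation per channel:
    dOD(lambda) = (eps_HbO2*dC_HbO2 + eps_HHb*dC_HHb) * DPF(lambda) * d,
    then I(t) = i0 * 10**(-dOD(t)). Round-tripping through the inverse
    conversion recovers the concentrations to numerical precision.

    ``params_short``/``params_long`` are :class:`nirsrls.mbll.MBLLParameters`
    with the respective source-detector separations.
    """
    from .mbll import forward_od  # local import: avoids module cycle

    def channel(hbo2: SampledSeries, hhb: SampledSeries, params):
        od760, od850 = forward_od(hbo2, hhb, params)
        return (
            hbo2.with_values(i0 * 10.0 ** (-od760.values)),
            hbo2.with_values(i0 * 10.0 ** (-od850.values)),
        )

    i760_s, i850_s = channel(rec.hbo2_short, rec.hhb_short, params_short)
    i760_l, i850_l = channel(rec.hbo2_long, rec.hhb_long, params_long)
    return IntensityRecording(
        i760_short=i760_s,
        i850_short=i850_s,
        i760_long=i760_l,
        i850_long=i850_l,
        baseline_duration_s=rec.baseline_duration_s,
    )
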