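# Methods

`nirsrls` recovers block-design evoked hemodynamic responses from
two-distance continuous-wave fNIRS recordings. This note documents the
models, the defaults and why they have the values they do, what the
synthetic generator does and does not emulate, and the numerical choices.

## Measurement model

A source-detector pair at short separation (1.3 cm) samples scalp and
skull only; a pair at long separation (3.5 cm) additionally samples
cortex. Both see the same systemic physiological oscillations — cardiac
pulsation (~1.2 Hz), respiration (~0.25 Hz) and Mayer waves (~0.1 Hz) —
while only the long channel carries the stimulus-evoked response,
attenuated because the activated cortical volume is a small fraction of
the optically sampled volume (partial volume effect).

### Modified Beer-Lambert law

Optical-density changes relative to the baseline-mean intensity,
ΔOD(λ,t) = −log10(I(t)/Ī_baseline), are converted per sample by solving

    ΔOD(λ) = [ε_HbO2(λ) ΔC_HbO2 + ε_HHb(λ) ΔC_HHb] · DPF(λ) · d

for the two chromophores, with ε the molar extinction coefficients
(1/(mM·cm), packaged table from the standard compiled hemoglobin
spectra: 760 nm → 0.5864/1.5485, 850 nm → 1.0580/0.6913), d the
geometric separation in cm and DPF the differential pathlength factor.
DPF defaults to 6.0 at both wavelengths (a common adult-head
convention) and is configurable per wavelength, as is the extinction
table — no single authoritative tabulation exists, so the constants
live in a swappable text file.

Before conversion a slow multiplicative source drift can be removed:
a straight line is fitted to log10-intensity **over the baseline span
only** and the whole record is divided by the fitted relative trend.
Restricting the fit to the baseline guarantees evoked changes can never
be regressed out; the cost is that only drifts which are log-linear
over the record are removed exactly.

### RLS interference cancellation

The long channel d(n) is modelled as an FIR-filtered copy of the short
channel plus the evoked signal. The FIR weights (order N = 16) are
estimated online by exponentially weighted recursive least squares with
forgetting factor λ = 0.999, zero initial weights, and initial
inverse-correlation matrix P₀ = p0_scale·I with p0_scale = 100 — large
enough that P is data-dominated within seconds at these signal scales
while avoiding an enormous initial transient. The a-priori error
e(n) = d(n) − wᵀx(n) is the cleaned output, the standard convention for
interference cancellers. The regressor stacks current and past
reference samples only (causal), so the filter is usable in real time.
λ = 0.999 at 10 Hz gives an effective memory of ~100 s, slow enough
not to track the evoked response itself but fast enough to follow the
non-stationarity of physiological rhythms. P is re-symmetrized after
every rank-one update so round-off cannot accumulate asymmetry.

With λ = 1 and large p0_scale the recursion reduces to batch least
squares; the test suite checks the final weights against numpy's
independent solver to 1e−6.

The conventional comparison method is a zero-phase (forward-backward)
4th-order Butterworth low-pass at 0.125 Hz.

### Partial volume correction

Measured concentration changes are multiplied by the partial volume
effect factor 9.15 (a photon-transport-derived constant taken as
given; estimating it is out of scope). The correction is a pure scale
and therefore provably cannot change the CNR statistic.

## Evaluation

* **Block average** — epochs of one stim+rest period starting at each
  stimulus onset, re-baselined by the mean of the 2 s preceding each
  onset (the convention is not standardized; a pre-onset window keeps
  the re-baselining independent of the response itself), then averaged.
* **PSD** — a single Hann-windowed, density-scaled periodogram of 4000
  task-period samples (400 s at 10 Hz), resolution 0.0025 Hz. Welch
  averaging is deliberately not used: the signal bands are 0.012 Hz
  wide and segmenting would destroy the needed resolution. The mean is
  removed before windowing; otherwise leakage from the large DC offset
  of a one-sided evoked series swamps the 0.025 Hz bin.
* **CNR** — signal energy integrates the PSD over 0.019–0.031 Hz
  (paradigm fundamental) and 0.044–0.056 Hz (second harmonic); noise
  energy over the rest of (0, 5] Hz. Bin membership is by bin centre in
  the closed interval; the DC bin is excluded from both energies (a
  baseline offset is not interference). CNR% = 100·√(E_s/E_n) — the
  ratio-of-energies reading, consistent with values exceeding 100%.

## Synthetic generator

The generator emulates the study conditions: 10 Hz sampling (the noise
band extends to 5 Hz, so Nyquist must be ≥ 5 Hz; 4000 points is then
exactly the 400 s task span), a 200 s quiet baseline, and 10 blocks of
20 s stimulus / 20 s rest (fundamental 0.025 Hz).

**Interference** is a sum of three sinusoids (defaults 1.2 Hz / 0.30 µM
cardiac, 0.25 Hz / 0.15 µM respiratory, 0.10 Hz / 0.20 µM Mayer) whose
instantaneous frequency carries per-sample Gaussian jitter (relative sd
0.02, i.e. a phase random walk) and whose amplitude is modulated by
1 + 0.1·sin(2π·0.01 t + ψ). One realization is shared by both channels
(unit coupling into the long channel); independent white sensor noise
(sd 0.097 µM) decorrelates them. HHb interference is the HbO2
realization divided by 3 — physiological oscillations are predominantly
an HbO2 phenomenon; the factor 3 encodes the direction, its magnitude
is an invented convention.

**Calibration.** With unit coupling the expected baseline correlation
is v/(v+σ²) with v the interference variance and σ the noise sd. The
default amplitudes give v ≈ 0.0766 µM²; σ = 0.097 µM then yields
r ≈ 0.890. These constants were fixed once from that closed form.

**Evoked response** — a first-order exponential rise/fall (τ = 5 s
both ways) toward a drive that switches on 4 s after stimulus onset
and off 6 s after stimulus offset. This matches the delay/return facts
the paradigm is known for while keeping a closed-form plateau for
testing; it is deliberately simpler than a canonical
gamma-function HRF. Cortical-scale amplitudes default to +7.0 µM HbO2
and −2.3 µM HHb — order-of-magnitude choices for a strong sensory
activation (the long channel sees amplitude/9.15 ≈ 0.77 µM); both are
configuration-exposed since no measured values exist to pin them.

**What it does not emulate:** motion artifacts, heterogeneous coupling
across frequencies (the channels share one scalar gain, which makes the
FIR identification easier than scalp physiology may be), non-Gaussian
sensor noise, multi-subject variability, and photon-transport realism
(intensities come from the forward Beer-Lambert model, not a layered
tissue simulation). Passing tests therefore demonstrate correctness of
the algorithms and the expected qualitative behaviour — large CNR gain
for HbO2, marginal gain for HHb, tenfold cardiac-band suppression — not
performance on real recordings.

## Problem sizes and determinism

Tests and the acceptance script use the full study geometry (6000
samples per channel) over 20 fixed seeds; stochastic checks either
average over the seeds or count successes (≥95% of seeds). Every
random quantity flows from an explicit integer seed through numpy's
`default_rng`; identical (parameters, seed) reproduce recordings bit
for bit, and pipeline artifacts are byte-identical across reruns.

## Known limitations

* The RLS inner loop is pure Python/numpy (≈0.1 s per 6000-sample
  channel) — fine at this scale, not tuned for long recordings.
* Drift correction assumes log-linear drift; slow physiological trends
  in the baseline bias the fit slightly (white noise alone contributes
  a ~1e−6/s slope uncertainty on a 200 s baseline).
* Only two wavelengths and two chromophores; no absolute oximetry, no
  scattering-change terms.
* The CSV reader requires strictly uniform time stamps; irregularly
  sampled input must be resampled upstream.
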