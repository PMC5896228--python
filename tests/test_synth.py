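"""Synthetic-recording generator: paradigm timing, evoked shape, statistics."""

import numpy as np
import pytest
from scipy.signal import periodogram

from nirsrls import (
    BlockDesign,
    EvokedResponse,
    InterferenceModel,
    MBLLParameters,
    SampledSeries,
    boxcar_stimulus,
    evoked_waveform,
    forward_intensities,
    generate_recording,
    intensity_to_od,
    od_to_concentration,
)


class TestBoxcarStimulus:
    def test_study_paradigm_length_and_fundamental(self):
        design = BlockDesign(20, 20, 10, 200)
        stim = boxcar_stimulus(design, fs=10.0)
        assert len(stim) == (200 + 10 * 40) * 10
        assert design.fundamental_hz == pytest.approx(0.025)
        # baseline all zero, first stimulus sample at 200 s
        assert not stim.values[:2000].any()
        assert stim.values[2000] == 1.0
        assert stim.values.sum() == 10 * 20 * 10  # total stimulated samples

    def test_minimal_design_sample_pattern(self):
        stim = boxcar_stimulus(BlockDesign(1, 1, 1, 0), fs=2.0)
        assert np.array_equal(stim.values, [1, 1, 0, 0])

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_blocks=0), dict(stim_duration_s=0), dict(rest_duration_s=-1)],
    )
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BlockDesign(**kwargs)

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(ValueError):
            boxcar_stimulus(BlockDesign(), fs=0.0)


class TestEvokedWaveform:
    def test_no_stimulus_no_response(self):
        stim = SampledSeries(np.zeros(100), fs=10.0)
        hbo2, hhb = evoked_waveform(stim, EvokedResponse())
        assert not hbo2.values.any() and not hhb.values.any()

    def test_plateau_reaches_amplitudes(self):
        # one long epoch: first-order step response saturates at the amplitudes
        resp = EvokedResponse(hbo2_amp=1.0, hhb_amp=-0.3, rise_tau_s=5.0)
        stim = SampledSeries(np.r_[np.zeros(50), np.ones(1000)], fs=10.0)
        hbo2, hhb = evoked_waveform(stim, resp)
        # well past onset delay + 5 rise time constants
        assert hbo2.values[-1] == pytest.approx(1.0, rel=0.01)
        assert hhb.values[-1] == pytest.approx(-0.3, rel=0.01)
        assert np.all(np.sign(hhb.values[60:]) == -np.sign(hbo2.values[60:]))

    def test_response_lags_onset_by_at_least_delay(self):
        resp = EvokedResponse(onset_delay_s=4.0)
        stim = boxcar_stimulus(BlockDesign(20, 20, 1, 10), fs=10.0)
        hbo2, _ = evoked_waveform(stim, resp)
        onset_idx = 100  # 10 s baseline
        assert not hbo2.values[: onset_idx + 40].any()  # quiet until onset+4 s

    def test_non_binary_stimulus_rejected(self):
        with pytest.raises(ValueError):
            evoked_waveform(SampledSeries(np.full(10, 0.5), 10.0), EvokedResponse())


class TestGenerateRecording:
    def test_degenerate_generator_isolates_evoked(self, quiet_recording):
        rec, truth = quiet_recording
        np.testing.assert_allclose(
            rec.hbo2_long.values, truth.hbo2_evoked.values / 9.15, atol=1e-15
        )
        assert not rec.hbo2_short.values.any()
        assert not rec.hhb_short.values.any()

    def test_ground_truth_zero_during_baseline(self, default_recording):
        _, truth = default_recording
        assert not truth.hbo2_evoked.values[:2000].any()
        assert truth.stimulus_onsets[0] == 200.0
        assert len(truth.stimulus_onsets) == 10

    def test_seed_reproducibility_contract(self, design):
        args = (design, InterferenceModel(), EvokedResponse())
        a, _ = generate_recording(*args, seed=7)
        b, _ = generate_recording(*args, seed=7)
        c, _ = generate_recording(*args, seed=8)
        np.testing.assert_array_equal(a.hbo2_long.values, b.hbo2_long.values)
        assert not np.array_equal(a.hbo2_long.values, c.hbo2_long.values)

    def test_seed_is_mandatory(self, design):
        with pytest.raises(ValueError, match="seed"):
            generate_recording(design, InterferenceModel(), EvokedResponse())

    def test_short_channel_spectrum_peaks_at_cardiac(self, design):
        interference = InterferenceModel()
        rec, _ = generate_recording(design, interference, EvokedResponse(), seed=5)
        f, p = periodogram(rec.hbo2_short.values, fs=10.0)
        f_peak = f[np.argmax(p)]
        half_width = 3 * interference.freq_jitter_sd * interference.cardiac_freq_hz
        assert abs(f_peak - interference.cardiac_freq_hz) <= half_width + f[1]

    def test_baseline_correlation_monotone_in_coupling_and_noise(self, design):
        from nirsrls import correlation

        def mean_r(**kwargs):
            rs = []
            for seed in range(3):
                rec, _ = generate_recording(
                    design, InterferenceModel(**kwargs), EvokedResponse(), seed=seed
                )
                rs.append(correlation(rec.hbo2_short, rec.hbo2_long, 200.0))
            return np.mean(rs)

        r_by_coupling = [mean_r(coupling=c) for c in (0.3, 1.0, 3.0)]
        assert r_by_coupling == sorted(r_by_coupling)
        r_by_noise = [mean_r(noise_sd=s) for s in (0.02, 0.097, 0.4)]
        assert r_by_noise == sorted(r_by_noise, reverse=True)

    def test_hhb_interference_scaled_down_by_ratio(self, design):
        interference = InterferenceModel(noise_sd=0.0)
        rec, _ = generate_recording(design, interference, EvokedResponse(), seed=1)
        ratio = interference.hbo2_hhb_interference_ratio
        np.testing.assert_allclose(
            rec.hhb_short.values, rec.hbo2_short.values / ratio, atol=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hbo2_amp=1.0, hhb_amp=-2.0),  # |HHb| must be smaller
            dict(hbo2_amp=1.0, hhb_amp=0.3),  # must be opposite sign
            dict(onset_delay_s=-1.0),
        ],
    )
    def test_invalid_evoked_response_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvokedResponse(**kwargs)


class TestForwardIntensities:
    short = MBLLParameters(separation_cm=1.3)
    long = MBLLParameters(separation_cm=3.5)

    def test_zero_concentrations_give_reference_intensity(self, quiet_recording):
        rec, _ = quiet_recording
        irec = forward_intensities(rec, self.short, self.long, i0=2.0)
        # short channel has zero concentration change -> constant I0
        np.testing.assert_allclose(irec.i760_short.values, 2.0)
        np.testing.assert_allclose(irec.i850_short.values, 2.0)

    def test_unit_hbo2_od_matches_extinction_pathlength(self):
        # 1 µM HbO2, 0 HHb: dOD(lambda) = eps_HbO2(lambda)*DPF*d*1e-3
        ones = SampledSeries(np.ones(10), fs=10.0)
        zeros = SampledSeries(np.zeros(10), fs=10.0)
        rec_kw = dict(baseline_duration_s=0.0)
        from nirsrls import ConcentrationRecording

        rec = ConcentrationRecording(
            hbo2_short=ones, hhb_short=zeros, hbo2_long=ones, hhb_long=zeros, **rec_kw
        )
        irec = forward_intensities(rec, self.short, self.long)
        eps760, eps850 = 0.5864, 1.0580  # packaged table, HbO2 column
        od760 = -np.log10(irec.i760_long.values[0])
        od850 = -np.log10(irec.i850_long.values[0])
        assert od760 == pytest.approx(eps760 * 6.0 * 3.5 * 1e-3, rel=1e-12)
        assert od850 == pytest.approx(eps850 * 6.0 * 3.5 * 1e-3, rel=1e-12)

    def test_round_trip_recovers_concentrations(self, default_recording):
        rec, _ = default_recording
        irec = forward_intensities(rec, self.short, self.long)
        od760 = intensity_to_od(irec.i760_long, 200.0)
        od850 = intensity_to_od(irec.i850_long, 200.0)
        hbo2, hhb = od_to_concentration(od760, od850, self.long)
        # intensity_to_od re-references to the baseline mean, so compare
        # after removing each series' baseline mean
        for got, want in ((hbo2, rec.hbo2_long), (hhb, rec.hhb_long)):
            np.testing.assert_allclose(
                got.values - got.values[:2000].mean(),
                want.values - want.values[:2000].mean(),
                atol=1e-9,
            )
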