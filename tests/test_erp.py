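"""EEG synthesis and the filter/epoch/reject/average/peak chain."""

import numpy as np
import pytest

from ictrain import assessment, eegsim, erp
from ictrain.eegsim import (
    ALL_CHANNELS,
    SCALP_SITES,
    ComponentSpec,
    EEGRecording,
    EvokedSimSpec,
    synthesize_eeg,
)

FS = 500.0


def _sequence(n_trials=20, isi=2500.0, rng=None):
    spec = assessment.AssessmentSpec(
        n_trials=n_trials, p_go=0.7 if n_trials % 10 == 0 else 1.0,
        isi_ms=isi,
    )
    return assessment.generate_sequence(spec, rng or np.random.default_rng(2))


def _noiseless_spec(**kwargs):
    defaults = dict(
        noise_sd_uv=0.0, latency_jitter_sd_ms=0.0, blink_rate_hz=0.0, nogo_gain=1.0
    )
    defaults.update(kwargs)
    return EvokedSimSpec(**defaults)


def _sine_recording(freq_hz, seconds=20.0):
    t = np.arange(0, seconds, 1 / FS)
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (len(ALL_CHANNELS), 1))
    return EEGRecording(
        data_uv=data, sfreq_hz=FS, ch_names=ALL_CHANNELS, events=[]
    )


class TestSynthesizeEEG:
    def test_noiseless_single_bump_lands_at_spec_latency(self):
        comp = ComponentSpec("N2", 250.0, 45.0, {s: 0.0 for s in SCALP_SITES} | {"Fz": -5.0})
        spec = _noiseless_spec(components=(comp,))
        seq = _sequence(n_trials=1)
        rec = synthesize_eeg(spec, seq, np.random.default_rng(0))
        fz = rec.data_uv[rec.channel_index("Fz")]
        onset_sample = rec.events[0][0]
        peak_sample = int(np.argmin(fz))
        assert fz.min() == pytest.approx(-5.0, rel=1e-6)
        assert peak_sample == onset_sample + int(round(0.250 * FS))

    def test_blink_free_synthesis_survives_rejection(self):
        seq = _sequence(n_trials=10)
        rec = synthesize_eeg(EvokedSimSpec(), seq, np.random.default_rng(1))
        epochs = erp.reject_epochs(erp.extract_epochs(erp.lowpass_filter(rec)))
        assert epochs.n_accepted == len(epochs)

    def test_blink_spec_must_exceed_rejection_threshold(self):
        with pytest.raises(ValueError):
            EvokedSimSpec(blink_rate_hz=0.1, blink_amp_uv=50.0)

    def test_reproducible_under_seed(self):
        seq = _sequence(n_trials=5)
        spec = EvokedSimSpec(blink_rate_hz=0.05)
        a = synthesize_eeg(spec, seq, np.random.default_rng(4))
        b = synthesize_eeg(spec, seq, np.random.default_rng(4))
        np.testing.assert_array_equal(a.data_uv, b.data_uv)


class TestLowpassFilter:
    @pytest.mark.parametrize(
        "freq,lo,hi",
        [
            (5.0, 0.95, 1.05),          # passband preserved
            (24.0, 0.708 / 10 ** (0.5 / 20), 0.708 * 10 ** (0.5 / 20)),  # -3 dB
            (60.0, 0.0, 0.2),           # stopband strongly attenuated
        ],
    )
    def test_magnitude_response(self, freq, lo, hi):
        rec = _sine_recording(freq)
        out = erp.lowpass_filter(rec)
        # FFT-free oracle: steady-state peak amplitude away from the edges
        steady = out.data_uv[0][2000:-2000]
        ratio = np.abs(steady).max()
        assert lo <= ratio <= hi

    def test_zero_phase_no_latency_shift(self):
        # a symmetric bump must stay centered after zero-phase filtering
        t = np.arange(0, 4, 1 / FS)
        bump = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        data = np.tile(bump, (len(ALL_CHANNELS), 1))
        rec = EEGRecording(data_uv=data, sfreq_hz=FS, ch_names=ALL_CHANNELS, events=[])
        out = erp.lowpass_filter(rec)
        assert abs(int(np.argmax(out.data_uv[0])) - int(np.argmax(bump))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            erp.lowpass_filter(_sine_recording(5.0), cutoff_hz=300.0)


class TestExtractEpochs:
    def test_constant_channel_zeroed_by_baseline(self):
        data = np.full((len(ALL_CHANNELS), 5000), 7.0)
        rec = EEGRecording(data_uv=data, sfreq_hz=FS, ch_names=ALL_CHANNELS,
                           events=[(1000, "go"), (3000, "nogo")])
        epochs = erp.extract_epochs(rec)
        np.testing.assert_allclose(epochs.data_uv, 0.0, atol=1e-12)

    def test_epoch_count_and_length(self):
        seq = _sequence(n_trials=20)
        rec = synthesize_eeg(EvokedSimSpec(), seq, np.random.default_rng(0))
        epochs = erp.extract_epochs(rec)
        assert len(epochs) == 20
        assert epochs.data_uv.shape[2] == int(round(1.0 * FS))  # 1000 ms window
        assert epochs.times_ms[0] == pytest.approx(-100.0)
        assert epochs.times_ms[-1] == pytest.approx(898.0)

    def test_step_at_onset_recovered_exactly(self):
        data = np.zeros((len(ALL_CHANNELS), 4000))
        onset = 2000
        data[:, onset:] = 4.2
        rec = EEGRecording(data_uv=data, sfreq_hz=FS, ch_names=ALL_CHANNELS,
                           events=[(onset, "go")])
        epochs = erp.extract_epochs(rec)
        post = epochs.times_ms >= 0
        np.testing.assert_allclose(epochs.data_uv[0][:, post], 4.2, atol=1e-12)
        np.testing.assert_allclose(epochs.data_uv[0][:, ~post], 0.0, atol=1e-12)

    def test_edge_event_dropped_with_warning(self):
        data = np.zeros((len(ALL_CHANNELS), 1000))
        rec = EEGRecording(data_uv=data, sfreq_hz=FS, ch_names=ALL_CHANNELS,
                           events=[(10, "go"), (400, "go")])
        with pytest.warns(UserWarning, match="dropped 1 event"):
            epochs = erp.extract_epochs(rec)
        assert len(epochs) == 1

    def test_matches_mne_epoching_oracle(self):
        mne = pytest.importorskip("mne")
        seq = _sequence(n_trials=10)
        rec = synthesize_eeg(EvokedSimSpec(), seq, np.random.default_rng(6))
        ours = erp.average_erp(erp.extract_epochs(rec))

        info = mne.create_info(list(rec.ch_names), FS, ch_types="eeg")
        raw = mne.io.RawArray(rec.data_uv * 1e-6, info, verbose="error")
        events = np.array([[s, 0, 1] for s, _ in rec.events])
        ep = mne.Epochs(
            raw, events, tmin=-0.1, tmax=0.898,
            baseline=(-0.1, -0.002), preload=True, verbose="error",
            reject=None, proj=False, event_repeated="error",
        )
        theirs = ep.get_data().mean(axis=0) * 1e6
        np.testing.assert_allclose(ours.data_uv, theirs, atol=1e-9)


class TestRejectEpochs:
    def _epochs_with_spike(self, value, channel="C3"):
        data = np.zeros((2, len(ALL_CHANNELS), 500))
        idx = ALL_CHANNELS.index(channel)
        data[0, idx, 250] = value
        return erp.EpochSet(
            data_uv=data,
            times_ms=np.arange(-50, 450) / FS * 1000.0,
            ch_names=ALL_CHANNELS,
            labels=np.array(["go", "go"], dtype=object),
            sfreq_hz=FS,
        )

    def test_101_uv_spike_rejected_100_kept(self):
        rejected = erp.reject_epochs(self._epochs_with_spike(101.0))
        assert list(rejected.accepted) == [False, True]
        kept = erp.reject_epochs(self._epochs_with_spike(100.0))
        assert list(kept.accepted) == [True, True]
        negative = erp.reject_epochs(self._epochs_with_spike(-101.0))
        assert list(negative.accepted) == [False, True]

    def test_eog_spike_does_not_reject(self):
        out = erp.reject_epochs(self._epochs_with_spike(500.0, channel="VEOG"))
        assert out.accepted.all()

    def test_injected_blinks_reject_exactly_those_epochs(self):
        seq = _sequence(n_trials=20)
        rec = synthesize_eeg(_noiseless_spec(), seq, np.random.default_rng(3))
        bad = [2, 7, 13]
        rec = eegsim.inject_blinks_at(rec, [rec.events[k][0] + 100 for k in bad])
        epochs = erp.reject_epochs(erp.extract_epochs(rec))
        assert sorted(np.flatnonzero(~epochs.accepted)) == bad
        assert (epochs.reject_reason[~epochs.accepted] != "").all()

    def test_monotone_in_threshold(self):
        seq = _sequence(n_trials=20)
        rec = synthesize_eeg(
            EvokedSimSpec(blink_rate_hz=0.2, noise_sd_uv=10.0),
            seq, np.random.default_rng(5),
        )
        base = erp.extract_epochs(rec)
        counts = [
            erp.reject_epochs(base, threshold_uv=th).n_accepted
            for th in (50.0, 100.0, 150.0, 1e6)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == len(base)

    def test_counting_conservation(self):
        seq = _sequence(n_trials=20)
        rec = synthesize_eeg(
            EvokedSimSpec(blink_rate_hz=0.2), seq, np.random.default_rng(8)
        )
        epochs = erp.reject_epochs(erp.extract_epochs(rec))
        assert epochs.n_accepted + (~epochs.accepted).sum() == len(epochs)


class TestAverageAndGrandMean:
    def _epochs(self, data, labels):
        return erp.EpochSet(
            data_uv=data,
            times_ms=np.arange(data.shape[2]) / FS * 1000.0,
            ch_names=ALL_CHANNELS,
            labels=np.array(labels, dtype=object),
            sfreq_hz=FS,
        )

    def test_single_epoch_average_is_identity(self, rng):
        data = rng.normal(size=(1, len(ALL_CHANNELS), 100))
        wave = erp.average_erp(self._epochs(data, ["go"]), "go")
        np.testing.assert_array_equal(wave.data_uv, data[0])
        assert wave.n_epochs == 1

    def test_symmetric_epochs_cancel(self):
        data = np.stack([np.ones((len(ALL_CHANNELS), 50)),
                         -np.ones((len(ALL_CHANNELS), 50))])
        wave = erp.average_erp(self._epochs(data, ["go", "go"]), "go")
        np.testing.assert_allclose(wave.data_uv, 0.0)

    def test_average_only_uses_accepted_epochs_of_condition(self, rng):
        data = rng.normal(size=(50, len(ALL_CHANNELS), 60))
        labels = ["go" if i % 2 else "nogo" for i in range(50)]
        epochs = self._epochs(data, labels)
        epochs.accepted[::5] = False
        wave = erp.average_erp(epochs, "go")
        mask = (np.array(labels) == "go") & epochs.accepted
        np.testing.assert_allclose(wave.data_uv, data[mask].mean(axis=0))

    def test_empty_condition_raises(self):
        data = np.zeros((1, len(ALL_CHANNELS), 10))
        with pytest.raises(erp.EmptyConditionError):
            erp.average_erp(self._epochs(data, ["go"]), "nogo")

    def test_grand_mean_matches_bruteforce(self, rng):
        waves = []
        arrays = []
        for _ in range(24):
            arr = rng.normal(size=(len(ALL_CHANNELS), 40))
            arrays.append(arr)
            waves.append(erp.ERPWaveform(arr, np.arange(40.0), ALL_CHANNELS, 1))
        gm = erp.grand_mean(waves)
        np.testing.assert_allclose(gm.data_uv, np.mean(arrays, axis=0))
        assert erp.grand_mean([waves[0]]).data_uv is not waves[0].data_uv

    def test_grand_mean_symmetric_inputs_cancel(self):
        a = erp.ERPWaveform(np.full((11, 10), 2.0), np.arange(10.0), ALL_CHANNELS, 1)
        b = erp.ERPWaveform(np.full((11, 10), -2.0), np.arange(10.0), ALL_CHANNELS, 1)
        np.testing.assert_allclose(erp.grand_mean([a, b]).data_uv, 0.0)

    def test_grand_mean_site_mismatch_rejected(self):
        a = erp.ERPWaveform(np.zeros((11, 10)), np.arange(10.0), ALL_CHANNELS, 1)
        other = tuple(reversed(ALL_CHANNELS))
        b = erp.ERPWaveform(np.zeros((11, 10)), np.arange(10.0), other, 1)
        with pytest.raises(ValueError):
            erp.grand_mean([a, b])


class TestQuantifyPeakLocked:
    def _waveform_with_bumps(self, site_peaks, width_ms=40.0):
        """site -> (latency_ms, amplitude): one Gaussian bump per site."""
        times = np.arange(-50, 450) * 2.0  # -100..898 ms at 500 Hz
        data = np.zeros((len(ALL_CHANNELS), len(times)))
        for site, (lat, amp) in site_peaks.items():
            idx = ALL_CHANNELS.index(site)
            data[idx] = amp * np.exp(-0.5 * ((times - lat) / width_ms) ** 2)
        return erp.ERPWaveform(data, times.astype(float), ALL_CHANNELS, 10)

    def test_noiseless_n2_construction(self):
        wave = self._waveform_with_bumps({"Fz": (250.0, -5.0), "F3": (250.0, -3.0)})
        peak = erp.quantify_peak_locked(wave, "N2")
        assert peak.latency_ms == pytest.approx(250.0)
        assert peak.amplitudes_uv["Fz"] == pytest.approx(-5.0)
        assert peak.amplitudes_uv["F3"] == pytest.approx(-3.0)
        assert not peak.boundary_peak

    def test_noiseless_p3_construction(self):
        wave = self._waveform_with_bumps({"Pz": (400.0, 8.0)})
        peak = erp.quantify_peak_locked(wave, "P3")
        assert peak.latency_ms == pytest.approx(400.0)
        assert peak.amplitudes_uv["Pz"] == pytest.approx(8.0)

    def test_amplitudes_read_at_reference_latency_not_local_peaks(self):
        # F3 peaks 40 ms later than Fz: its reported amplitude must be the
        # value AT the Fz latency, not its own maximum deviation
        wave = self._waveform_with_bumps({"Fz": (240.0, -6.0), "F3": (280.0, -6.0)})
        peak = erp.quantify_peak_locked(wave, "N2")
        assert peak.latency_ms == pytest.approx(240.0)
        expected_f3 = -6.0 * np.exp(-0.5 * ((240.0 - 280.0) / 40.0) ** 2)
        assert peak.amplitudes_uv["F3"] == pytest.approx(expected_f3)
        assert abs(peak.amplitudes_uv["F3"]) < 6.0

    def test_monotone_trace_flags_boundary_peak(self):
        times = np.arange(-50, 450) * 2.0
        data = np.zeros((len(ALL_CHANNELS), len(times)))
        data[ALL_CHANNELS.index("Fz")] = -times / 100.0  # decreasing over window
        wave = erp.ERPWaveform(data, times.astype(float), ALL_CHANNELS, 5)
        peak = erp.quantify_peak_locked(wave, "N2")
        assert peak.latency_ms == pytest.approx(300.0)
        assert peak.boundary_peak

    def test_tie_broken_to_earliest_sample(self):
        times = np.arange(-50, 450) * 2.0
        data = np.zeros((len(ALL_CHANNELS), len(times)))
        fz = ALL_CHANNELS.index("Fz")
        for lat in (220.0, 260.0):
            data[fz, np.argmin(np.abs(times - lat))] = -4.0
        wave = erp.ERPWaveform(data, times.astype(float), ALL_CHANNELS, 5)
        assert erp.quantify_peak_locked(wave, "N2").latency_ms == pytest.approx(220.0)

    def test_lock_site_and_window_overridable(self):
        wave = self._waveform_with_bumps({"Fz": (400.0, 7.0), "Pz": (450.0, 7.0)})
        peak = erp.quantify_peak_locked(wave, "P3", lock_site="Fz")
        assert peak.reference_site == "Fz"
        assert peak.latency_ms == pytest.approx(400.0)

    def test_missing_reference_channel_rejected(self):
        wave = erp.ERPWaveform(
            np.zeros((2, 500)), np.arange(-50, 450) * 2.0, ("F3", "F4"), 1
        )
        with pytest.raises(ValueError):
            erp.quantify_peak_locked(wave, "N2")


class TestParameterRecovery:
    def test_noiseless_pipeline_recovers_spec_exactly(self):
        seq = _sequence(n_trials=20)
        spec = _noiseless_spec()
        rec = synthesize_eeg(spec, seq, np.random.default_rng(0))
        epochs = erp.reject_epochs(erp.extract_epochs(rec))
        wave = erp.average_erp(epochs)
        n2 = erp.quantify_peak_locked(wave, "N2")
        p3 = erp.quantify_peak_locked(wave, "P3")
        assert n2.latency_ms == pytest.approx(250.0, abs=2.0)
        assert p3.latency_ms == pytest.approx(420.0, abs=2.0)
        assert n2.amplitudes_uv["Fz"] == pytest.approx(-6.0, rel=1e-3)
        assert p3.amplitudes_uv["Pz"] == pytest.approx(10.0, rel=1e-3)
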