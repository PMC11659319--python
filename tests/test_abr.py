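"""Epoch processing: rejection, averaging/filtering, peak picking."""

import numpy as np
import pytest

from abrcog.abr import (
    ABRWaveform,
    EpochSet,
    QC_BOUNDARY,
    QC_CLEAN,
    QC_NO_PEAK,
    average_and_filter,
    extract_features,
    pick_wave,
    process_epoch_set,
    reject_artifacts,
)
from abrcog.schema import InputError
from abrcog.synthetic import EpochParams, generate_epoch_set, wave_template

FS = 24000.0


def make_epochs(data, fs=FS):
    return EpochSet(data=np.atleast_2d(np.asarray(data, float)), sampling_rate=fs)


def times(n, fs=FS):
    return np.arange(n) / fs * 1000.0


class TestRejectArtifacts:
    def test_sweep_exceeding_threshold_rejected(self):
        n = 256
        data = np.zeros((2, n))
        data[1, 100] = 30.0  # 30 µV > 23.8 µV
        out = reject_artifacts(make_epochs(data))
        assert out.accepted_mask.tolist() == [True, False]
        np.testing.assert_array_equal(out.data, data)  # data untouched

    def test_all_zero_sweeps_accepted(self):
        out = reject_artifacts(make_epochs(np.zeros((5, 64))))
        assert out.accepted_mask.all()

    def test_matches_generator_artifact_mask(self):
        es = generate_epoch_set(EpochParams(artifact_rate=0.2, n_sweeps=500, noise_sd=2.0, seed=7))
        out = reject_artifacts(es)
        np.testing.assert_array_equal(~out.accepted_mask, es.meta["artifact_mask"])

    def test_idempotent(self):
        es = generate_epoch_set(EpochParams(artifact_rate=0.2, n_sweeps=300, seed=1))
        once = reject_artifacts(es)
        twice = reject_artifacts(once)
        np.testing.assert_array_equal(once.accepted_mask, twice.accepted_mask)

    def test_empty_set_errors(self):
        with pytest.raises(InputError):
            make_epochs(np.empty((0, 10)))


class TestAverageAndFilter:
    def test_identical_sweeps_average_to_one_sweep(self):
        tmpl = wave_template(times(256), 6.0, 0.23, 0.5)
        es = make_epochs(np.tile(tmpl, (100, 1)))
        with pytest.warns(UserWarning):  # below default min_sweeps
            wave = average_and_filter(es)
        single = average_and_filter(make_epochs(tmpl[None, :]), min_sweeps=1)
        np.testing.assert_allclose(wave.samples, single.samples, atol=1e-12)
        assert wave.n_sweeps_accepted == 100

    def test_noise_suppression_follows_sqrt_n(self, rng):
        n_sweeps = 4000
        data = rng.standard_normal((n_sweeps, 256))
        wave = average_and_filter(make_epochs(data), min_sweeps=1)
        rms_avg = np.sqrt(np.mean(wave.samples**2))
        rms_one = np.sqrt(np.mean(data[0] ** 2))
        # bandpass removes some noise power too, so the averaged RMS can
        # only be at or below the 1/sqrt(n) white-noise prediction
        assert rms_avg < rms_one / np.sqrt(n_sweeps) * 1.2

    def test_stopband_rejection_of_low_frequency(self):
        t_s = np.arange(2560) / FS
        sine = np.sin(2 * np.pi * 10.0 * t_s)  # 10 Hz, far below 100 Hz corner
        wave = average_and_filter(make_epochs(sine[None, :]), min_sweeps=1)
        assert np.sqrt(np.mean(wave.samples**2)) < 0.01 * np.sqrt(np.mean(sine**2))

    def test_zero_accepted_sweeps_errors(self):
        es = make_epochs(np.full((3, 64), 100.0))
        rejected = reject_artifacts(es)
        with pytest.raises(InputError):
            average_and_filter(rejected, min_sweeps=1)

    def test_zero_phase_preserves_peak_latency(self):
        tmpl = wave_template(times(256), 6.0, 0.3, 0.5)
        wave = average_and_filter(make_epochs(tmpl[None, :]), min_sweeps=1)
        assert abs(int(wave.samples.argmax()) - int(tmpl.argmax())) <= 1


class TestPickWave:
    def test_single_bump_latency_and_amplitude(self):
        n = 256
        tmpl = wave_template(times(n), 6.0, 0.4, 0.5)
        wf = ABRWaveform(samples=tmpl, sampling_rate=FS, n_sweeps_accepted=1)
        lat, amp, flag = pick_wave(wf, (5.1, 6.4))
        assert lat == pytest.approx(6.0, abs=0.5 / FS * 1000)
        assert amp == pytest.approx(0.4, rel=1e-6)
        assert flag == QC_CLEAN

    def test_flat_waveform_flags_no_peak(self):
        wf = ABRWaveform(samples=np.zeros(256), sampling_rate=FS, n_sweeps_accepted=1)
        lat, amp, flag = pick_wave(wf, (5.1, 6.4))
        assert amp == 0.0
        assert flag == QC_NO_PEAK

    def test_boundary_peak_flagged(self):
        n = 256
        ramp = np.linspace(0, 1, n)  # maximum at the window's right edge
        wf = ABRWaveform(samples=ramp, sampling_rate=FS, n_sweeps_accepted=1)
        _, _, flag = pick_wave(wf, (5.1, 6.4))
        assert flag == QC_BOUNDARY

    def test_window_outside_waveform_errors(self):
        wf = ABRWaveform(samples=np.zeros(32), sampling_rate=FS, n_sweeps_accepted=1)
        with pytest.raises(InputError):
            pick_wave(wf, (5.1, 6.4))  # waveform spans only ~1.3 ms


class TestExtractFeatures:
    def waveform_with_waves(self, lat_i=1.8, lat_v=6.05, amp_i=0.1, amp_v=0.23):
        t = times(256)
        tmpl = wave_template(t, lat_i, amp_i, 0.3) + wave_template(t, lat_v, amp_v, 0.5)
        return ABRWaveform(samples=tmpl, sampling_rate=FS, n_sweeps_accepted=2000)

    def test_iv_latency_difference(self):
        f = extract_features(self.waveform_with_waves())
        assert f.iv_latency_difference == pytest.approx(4.25, abs=2 / FS * 1000)
        assert f.iv_latency_difference == pytest.approx(
            f.wave_v_latency - f.wave_i_latency, abs=1e-12
        )

    def test_equal_amplitudes_give_zero_log_ratio(self):
        f = extract_features(self.waveform_with_waves(amp_i=0.2, amp_v=0.2))
        assert f.log_vi_amplitude_ratio == pytest.approx(0.0, abs=0.15)

    def test_zero_wave_i_amplitude_makes_ratio_missing(self):
        f = extract_features(self.waveform_with_waves(amp_i=0.0))
        assert np.isnan(f.log_vi_amplitude_ratio)
        assert "vi_ratio" in f.qc_flags
        assert not f.is_clean

    def test_too_short_waveform_errors(self):
        wf = ABRWaveform(samples=np.zeros(64), sampling_rate=FS, n_sweeps_accepted=1)
        with pytest.raises(InputError):
            extract_features(wf)


class TestEndToEnd:
    def test_planted_features_recovered_through_full_chain(self):
        """At realistic single-sweep noise (5 µV) the averaged response keeps
        ~0.05 µV residual noise, so single-set picks jitter; the mean over
        seeds must recover the planted wave V within that jitter."""
        lats, amps = [], []
        for seed in range(10):
            p = EpochParams(
                waves=((1.8, 0.10, 0.3), (6.05, 0.23, 0.5)),
                noise_sd=5.0, artifact_rate=0.05, n_sweeps=2400, seed=seed,
            )
            f = process_epoch_set(generate_epoch_set(p))
            lats.append(f.wave_v_latency)
            amps.append(f.wave_v_amplitude)
        assert np.mean(lats) == pytest.approx(6.05, abs=0.12)
        assert np.mean(amps) == pytest.approx(0.23, rel=0.35)
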