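"""Waveform-to-NNI pipeline: trimming, filtering, peak detection, outlier handling."""

import numpy as np
import pytest
from scipy import signal

from ppgstress import (
    InsufficientDataError,
    NNISeries,
    PhysioState,
    PPGRecording,
    PPISeries,
    PreprocessConfig,
    bandpass,
    detect_peaks,
    generate_nni_series,
    preprocess,
    remove_outlier_ppi,
    render_ppg,
    replace_removed,
    trim_recording,
)

FS = 255.0


def _sine_recording(freq: float, duration: float = 60.0, fs: float = FS) -> PPGRecording:
    t = np.arange(int(duration * fs)) / fs
    return PPGRecording(samples=np.sin(2 * np.pi * freq * t), fs=fs)


def _ppi(intervals, mask=None):
    intervals = np.asarray(intervals, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    mask = np.zeros(intervals.size, bool) if mask is None else np.asarray(mask, bool)
    return PPISeries(peak_times=times, intervals=intervals, removal_mask=mask)


class TestTrim:
    def test_default_trim_of_six_minutes_leaves_five(self):
        rec = PPGRecording(samples=np.random.default_rng(0).normal(size=int(360 * FS)), fs=FS)
        out = trim_recording(rec, 30.0, 30.0)
        assert out.samples.size == 76_500  # 300 s at 255 Hz
        assert out.duration_s == pytest.approx(300.0)
        assert out.t0 == pytest.approx(30.0)

    def test_zero_trim_is_identity(self):
        rec = _sine_recording(1.0, duration=10.0)
        out = trim_recording(rec, 0.0, 0.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_too_short_recording_rejected(self):
        rec = _sine_recording(1.0, duration=50.0)
        with pytest.raises(InsufficientDataError):
            trim_recording(rec, 30.0, 30.0)


class TestBandpass:
    @staticmethod
    def _gain(freq: float) -> float:
        """Independent oracle: squared Butterworth magnitude (filtfilt = |H|^2)."""
        sos = signal.butter(4, [0.5, 3.0], btype="bandpass", fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
        return float(np.abs(h[0]) ** 2)

    @staticmethod
    def _output_amplitude(freq: float) -> float:
        out = bandpass(_sine_recording(freq, duration=120.0))
        mid = out.samples[int(30 * FS): int(90 * FS)]  # avoid edge transients
        return float(np.max(np.abs(mid)))

    def test_passband_tone_preserved(self):
        assert self._output_amplitude(1.5) >= 0.95

    @pytest.mark.parametrize("freq", [0.1, 10.0])
    def test_stopband_tone_attenuated_to_response_oracle(self, freq):
        amp = self._output_amplitude(freq)
        assert amp <= 0.1
        assert amp <= self._gain(freq) + 0.01

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_sine_recording(1.0), low=0.5, high=200.0)

    def test_length_and_fs_preserved(self):
        rec = _sine_recording(1.0, duration=20.0)
        out = bandpass(rec)
        assert out.samples.size == rec.samples.size
        assert out.fs == rec.fs


class TestDetectPeaks:
    def test_constant_train_intervals_within_two_samples(self):
        truth = generate_nni_series(PhysioState(name="rest", mean_rr=1000.0), 122.0, seed=0)
        rec = render_ppg(truth, fs=FS, duration_s=120.5)
        # trim as the pipeline does: un-trimmed ends carry filtfilt edge
        # transients that distort the boundary beats
        ppi = detect_peaks(bandpass(trim_recording(rec, 10.0, 10.0)))
        tol = 2000.0 / FS
        assert np.all(np.abs(ppi.intervals - 1000.0) <= tol)

    def test_peak_count_matches_ground_truth(self, clean_recording):
        rec, truth = clean_recording
        filtered = bandpass(trim_recording(rec, 30.0, 30.0))
        ppi = detect_peaks(filtered)
        n_true = np.sum((truth.pulse_times >= 30.0) & (truth.pulse_times <= 330.0))
        assert abs(ppi.peak_times.size - n_true) <= 1

    def test_flat_signal_rejected(self):
        rec = PPGRecording(samples=np.ones(1000), fs=FS)
        with pytest.raises(InsufficientDataError):
            detect_peaks(rec)

    def test_peak_times_strictly_increasing(self, clean_recording):
        rec, _ = clean_recording
        ppi = detect_peaks(bandpass(trim_recording(rec, 30.0, 30.0)))
        assert np.all(np.diff(ppi.peak_times) > 0)


class TestOutlierRemoval:
    def test_constant_series_is_noop(self):
        out = remove_outlier_ppi(_ppi([800.0] * 5), T=2.0)
        assert not out.removal_mask.any()

    def test_single_outlier_flagged_by_hand_arithmetic(self):
        # [800]*10 + [1600]: mean 872.7, population sd 241.2, z(1600) = 3.01 >= 2
        out = remove_outlier_ppi(_ppi([800.0] * 10 + [1600.0]), T=2.0)
        expected = np.zeros(11, bool)
        expected[10] = True
        np.testing.assert_array_equal(out.removal_mask, expected)

    def test_huge_threshold_flags_nothing(self):
        rng = np.random.default_rng(3)
        out = remove_outlier_ppi(_ppi(rng.uniform(600, 1000, 50)), T=10.0)
        assert not out.removal_mask.any()

    def test_intervals_unchanged_only_mask_set(self):
        intervals = [800.0] * 10 + [1600.0]
        out = remove_outlier_ppi(_ppi(intervals), T=2.0)
        np.testing.assert_array_equal(out.intervals, intervals)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            remove_outlier_ppi(_ppi([800.0, 900.0]), T=2.0)


class TestReplaceRemoved:
    def test_single_mask_replaced_by_neighbour_median(self):
        out = replace_removed(_ppi([800.0, 2000.0, 820.0], [False, True, False]))
        np.testing.assert_allclose(out.intervals, [800.0, 810.0, 820.0])
        np.testing.assert_array_equal(out.replaced, [False, True, False])

    def test_masked_run_uses_flanking_survivors(self):
        out = replace_removed(_ppi([800.0, 1.0, 1.0, 900.0], [False, True, True, False]))
        np.testing.assert_allclose(out.intervals, [800.0, 850.0, 850.0, 900.0])

    def test_boundary_mask_copies_nearest_survivor(self):
        out = replace_removed(_ppi([5000.0, 700.0, 710.0], [True, False, False]))
        np.testing.assert_allclose(out.intervals, [700.0, 700.0, 710.0])

    def test_all_masked_rejected(self):
        with pytest.raises(InsufficientDataError):
            replace_removed(_ppi([800.0, 810.0], [True, True]))

    def test_length_preserved(self):
        out = replace_removed(_ppi([800.0, 2000.0, 820.0, 830.0], [False, True, False, False]))
        assert len(out) == 4


class TestEndToEnd:
    def test_clean_recording_recovered_within_two_sample_periods(self, clean_recording):
        rec, truth = clean_recording
        nni = preprocess(rec)
        t = truth.pulse_times
        true_rr = np.diff(t[(t >= 30.0) & (t <= 330.0)]) * 1000.0
        assert abs(len(nni) - true_rr.size) <= 2
        m = min(len(nni), true_rr.size)
        assert np.max(np.abs(nni.intervals[:m] - true_rr[:m])) <= 2000.0 / FS

    def test_pipeline_deterministic(self, clean_recording):
        rec, _ = clean_recording
        a, b = preprocess(rec), preprocess(rec)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        np.testing.assert_array_equal(a.replaced, b.replaced)

    def test_clean_recordings_have_zero_replaced_flags(self, clean_state):
        # bounded (sinusoidal) interval distribution keeps max |z| < 2
        for seed in range(20):
            truth = generate_nni_series(clean_state, 360.0, seed=300 + seed)
            nni = preprocess(render_ppg(truth, fs=FS, duration_s=360.0))
            assert nni.replaced.sum() == 0

    def test_injected_artifacts_are_flagged(self, clean_state):
        truth = generate_nni_series(clean_state, 360.0, seed=77)
        rec = render_ppg(truth, fs=FS, duration_s=360.0)
        # inject 3 transient spikes mid-recording, each mid-way between beats
        samples = rec.samples.copy()
        t = np.arange(samples.size) / FS
        mids = (truth.pulse_times[:-1] + truth.pulse_times[1:]) / 2.0
        spike_times = [m for m in mids if 60.0 < m < 300.0][::40][:3]
        assert len(spike_times) == 3
        for st in spike_times:
            samples += 3.0 * np.exp(-0.5 * ((t - st) / 0.03) ** 2)
        nni = preprocess(PPGRecording(samples=samples, fs=FS))
        assert nni.replaced.sum() >= 3

    def test_replacement_preserves_interval_count(self, clean_recording):
        rec, _ = clean_recording
        filtered = bandpass(trim_recording(rec, 30.0, 30.0))
        ppi = remove_outlier_ppi(detect_peaks(filtered), T=0.8)  # force some flags
        assert len(replace_removed(ppi)) == ppi.intervals.size
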