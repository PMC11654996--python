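"""PPG/ECG beat detection: filter behaviour, round trips, latency, causality."""

import numpy as np
import pytest

from cardiosync import (BeatSeries, DetectorConfig, NoiseSpec, SignalTrace,
                        causal_bandpass, detect_ecg_rpeaks,
                        detect_ppg_beats_online, render_ecg, render_ppg,
                        simulate_beat_times)
from cardiosync.detection import OnlinePpgDetector

FS = 134.0


def _sine_trace(freq, duration=120.0, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return SignalTrace(np.sin(2 * np.pi * freq * t), fs, "ppg")


def _fft_amplitude(x, fs, freq):
    # steady-state amplitude at freq, skipping the filter transient
    seg = x[int(20 * fs):]
    spec = np.fft.rfft(seg * np.hanning(seg.size))
    freqs = np.fft.rfftfreq(seg.size, 1 / fs)
    return np.abs(spec[np.argmin(np.abs(freqs - freq))])


class TestCausalBandpass:
    def test_zero_in_zero_out(self):
        tr = SignalTrace(np.zeros(1000), FS, "ppg")
        out = causal_bandpass(tr)
        assert np.all(out.samples == 0)
        assert len(out) == len(tr) and out.sampling_rate == FS

    def test_passband_amplitude_preserved(self):
        tr = _sine_trace(1.2)
        out = causal_bandpass(tr)
        ratio = (_fft_amplitude(out.samples, FS, 1.2)
                 / _fft_amplitude(tr.samples, FS, 1.2))
        assert 0.9 <= ratio <= 1.1

    def test_baseline_wander_attenuated_20db(self):
        tr = _sine_trace(0.05, duration=240.0)
        out = causal_bandpass(tr)
        ratio = (_fft_amplitude(out.samples, FS, 0.05)
                 / _fft_amplitude(tr.samples, FS, 0.05))
        assert ratio < 0.1  # >= 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        tr = _sine_trace(1.0, duration=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            causal_bandpass(tr, DetectorConfig(bandpass_high_hz=80.0))

    def test_requires_ppg_channel(self):
        tr = SignalTrace(np.zeros(100), 240.0, "ecg")
        with pytest.raises(ValueError):
            causal_bandpass(tr)


class TestOnlinePpgDetection:
    def test_clean_60bpm_round_trip(self):
        truth = simulate_beat_times(60.0, 0.0, 60.0, seed=0)
        ppg = render_ppg(truth, FS, 0.25, duration_s=60.0)
        res = detect_ppg_beats_online(ppg)
        assert abs(len(res.beats) - 60) <= 1
        # every detection within 30 ms of a true peak (truth + ptt)
        expected = truth.times + 0.25
        for bt in res.beats.times:
            assert np.min(np.abs(expected - bt)) <= 0.030

    def test_masked_pulse_reduces_count_by_one(self):
        truth = simulate_beat_times(60.0, 0.0, 30.0, seed=0)
        ppg = render_ppg(truth, FS, 0.25, duration_s=30.0)
        # sensor dropout: flatten a window covering exactly one pulse
        samples = ppg.samples.copy()
        masked_beat = truth.times[10] + 0.25
        lo, hi = int((masked_beat - 0.45) * FS), int((masked_beat + 0.45) * FS)
        samples[lo:hi] = 0.0
        intact = detect_ppg_beats_online(ppg)
        dropped = detect_ppg_beats_online(
            SignalTrace(samples, FS, "ppg"))
        assert len(dropped.beats) == len(intact.beats) - 1

    def test_flat_line_warns_and_returns_no_beats(self):
        tr = SignalTrace(np.zeros(int(10 * FS)), FS, "ppg")
        with pytest.warns(RuntimeWarning):
            res = detect_ppg_beats_online(tr)
        assert len(res.beats) == 0

    def test_short_trace_rejected(self):
        tr = SignalTrace(np.zeros(int(2 * FS)), FS, "ppg")
        with pytest.raises(ValueError):
            detect_ppg_beats_online(tr)

    def test_refractory_never_violated(self):
        truth = simulate_beat_times(90.0, 0.05, 60.0, seed=21)
        noise = NoiseSpec(baseline_wander_amp=0.3, white_noise_sd=0.1,
                          seed=22)
        ppg = render_ppg(truth, FS, 0.25, noise, duration_s=60.0)
        cfg = DetectorConfig()
        res = detect_ppg_beats_online(ppg, cfg)
        assert np.all(np.diff(res.beats.times) >= cfg.refractory_s - 1e-9)

    def test_streaming_equals_batch(self):
        truth = simulate_beat_times(70.0, 0.05, 30.0, seed=5)
        noise = NoiseSpec(white_noise_sd=0.05, seed=6)
        ppg = render_ppg(truth, FS, 0.25, noise, duration_s=30.0)
        batch = detect_ppg_beats_online(ppg)
        det = OnlinePpgDetector(FS, DetectorConfig())
        streamed = [t for x in ppg.samples
                    if (t := det.process(float(x))) is not None]
        np.testing.assert_allclose(batch.beats.times, streamed)
        np.testing.assert_allclose(batch.decision_latencies, det.latencies)

    def test_latency_budget_50ms_end_to_end(self):
        # emission time vs *true* waveform peak: filter lag + confirmation
        truth = simulate_beat_times(70.0, 0.05, 60.0, seed=11)
        ppg = render_ppg(truth, FS, 0.25, duration_s=60.0)
        cfg = DetectorConfig()
        res = detect_ppg_beats_online(ppg, cfg)
        expected = truth.times + 0.25
        for bt, lat in zip(res.beats.times, res.decision_latencies):
            true_peak = expected[np.argmin(np.abs(expected - bt))]
            emission = bt + lat
            assert 0.0 <= emission - true_peak <= cfg.max_decision_latency_s


class TestEcgRpeaks:
    def test_noise_free_round_trip_within_20ms(self, truth_60s,
                                               clean_ecg_60s):
        r = detect_ecg_rpeaks(clean_ecg_60s)
        assert len(r) == len(truth_60s)
        err = np.abs(r.times - truth_60s.times)
        assert np.max(err) <= 0.020

    def test_mild_noise_recovers_99_percent(self, truth_60s):
        noise = NoiseSpec(white_noise_sd=0.1, seed=8)
        ecg = render_ecg(truth_60s, 240.0, noise, duration_s=60.0)
        r = detect_ecg_rpeaks(ecg)
        matched = sum(np.min(np.abs(r.times - t)) <= 0.05
                      for t in truth_60s.times)
        assert matched / len(truth_60s) >= 0.99

    def test_flat_record_yields_no_peaks(self):
        tr = SignalTrace(np.zeros(2400), 240.0, "ecg")
        with pytest.warns(RuntimeWarning):
            r = detect_ecg_rpeaks(tr)
        assert len(r) == 0

    def test_requires_ecg_channel(self, clean_ppg_60s):
        with pytest.raises(ValueError):
            detect_ecg_rpeaks(clean_ppg_60s)


class TestDetectorConfig:
    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(bandpass_low_hz=8.0, bandpass_high_hz=0.5)

    def test_refractory_floor(self):
        with pytest.raises(ValueError):
            DetectorConfig(refractory_s=0.1)
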