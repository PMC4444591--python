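"""Median-threshold spike detection: noise estimator, filter, detector, raster."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroassay import (
    MEDIAN_NORM,
    MeaSimConfig,
    SignalRecording,
    SpikeDetectionParams,
    SpikeEventTable,
    bandpass_filter,
    detect_spikes,
    estimate_noise_sigma,
    generate_mea_recording,
    raster,
)

from conftest import make_noise_recording


class TestNoiseSigma:
    def test_all_zero_signal_gives_zero(self):
        assert estimate_noise_sigma(np.zeros(100)) == 0.0

    def test_alternating_unit_signal(self):
        # median(|x|) = 1 so sigma = 1/0.6745
        x = np.tile([-1.0, 1.0], 50)
        assert estimate_noise_sigma(x) == pytest.approx(1 / MEDIAN_NORM)
        assert estimate_noise_sigma(x) == pytest.approx(1.4826, abs=5e-4)

    def test_consistency_on_gaussian_noise(self):
        # median(|Z|) = 0.6745 * SD for a normal, so the estimate converges
        r = np.random.default_rng(42)
        x = r.normal(0, 5.0, 1_000_000)
        assert estimate_noise_sigma(x) == pytest.approx(5.0, rel=0.01)

    def test_robust_to_sparse_spikes(self):
        # inserting large rare deflections barely moves the estimate
        r = np.random.default_rng(3)
        x = r.normal(0, 5.0, 200_000)
        clean = estimate_noise_sigma(x)
        x[::2000] = 80.0
        assert estimate_noise_sigma(x) == pytest.approx(clean, rel=0.02)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.empty(0))


class TestBandpassFilter:
    fs = 20000.0

    def _tone(self, freq, amp=10.0, duration=1.0):
        t = np.arange(int(self.fs * duration)) / self.fs
        return SignalRecording(amp * np.sin(2 * np.pi * freq * t), self.fs)

    def test_dc_removed(self):
        rec = SignalRecording(np.full(20000, 42.0), self.fs)
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.signal)) < 1e-6
        assert out.filtered

    def test_in_band_tone_preserved(self):
        out = bandpass_filter(self._tone(1000.0))
        mid = out.signal[0, 5000:-5000]  # ignore filter edge transients
        assert np.max(np.abs(mid)) == pytest.approx(10.0, rel=0.05)

    def test_out_of_band_tone_rejected(self):
        out = bandpass_filter(self._tone(50.0))
        mid = out.signal[0, 5000:-5000]
        assert np.max(np.abs(mid)) < 1.0  # > 10x attenuation

    def test_band_above_nyquist_rejected(self):
        rec = self._tone(1000.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, band=(300.0, 12000.0))

    def test_shape_preserved(self, small_recording):
        rec, _, _ = small_recording
        out = bandpass_filter(rec)
        assert out.signal.shape == rec.signal.shape


class TestDetectSpikes:
    fs = 20000.0

    def test_zero_signal_empty_table(self):
        rec = SignalRecording(np.zeros((2, 10000)), self.fs, filtered=True)
        events = detect_spikes(rec)
        assert len(events) == 0

    def test_unfiltered_input_rejected(self):
        rec = SignalRecording(np.zeros((1, 1000)), self.fs, filtered=False)
        with pytest.raises(ValueError, match="filter"):
            detect_spikes(rec)

    def test_single_inserted_spike_recovered(self):
        # noise sigma 5 uV + one 40 uV spike -> exactly one event within 0.5 ms
        cfg = MeaSimConfig(
            n_channels=1, duration=2.0, noise_sigma=5.0, spike_amplitude=40.0,
            basal_rate=0.0, burst_rate=0.0, seed=5,
        )
        rec, _ = generate_mea_recording(cfg)
        t_true = 1.0
        from neuroassay import spike_template

        tpl, peak = spike_template(self.fs, 40.0)
        i0 = int(t_true * self.fs) - peak
        rec.signal[0, i0 : i0 + tpl.size] += tpl
        events = detect_spikes(bandpass_filter(rec))
        assert len(events) == 1
        assert abs(events.time[0] - t_true) <= 0.5e-3

    def test_refractory_merges_close_deflections(self):
        # two suprathreshold deflections 0.5 ms apart -> one event
        r = np.random.default_rng(0)
        x = r.normal(0, 5.0, 20000)
        for t0 in (0.5, 0.5005):  # 0.5 ms apart
            i = int(t0 * self.fs)
            x[i : i + 4] = -60.0
        rec = SignalRecording(x, self.fs, filtered=True)
        events = detect_spikes(rec)
        near = events.time[(events.time > 0.49) & (events.time < 0.52)]
        assert near.size == 1

    def test_exactly_one_refractory_interval_allowed(self):
        # events separated by exactly 1 ms are both kept (inclusive rule)
        x = np.zeros(20000)
        x[1000:1004] = -50.0
        x[1020:1024] = -50.0  # 20 samples = 1.0 ms later
        rec = SignalRecording(x, self.fs, filtered=True)
        events = detect_spikes(rec)
        assert len(events) == 2

    def test_threshold_scales_with_amplitude(self):
        # doubling the signal doubles T exactly -> identical detections
        rec = make_noise_recording(seed=9)
        cfg = SpikeDetectionParams()
        rec.filtered = True
        e1 = detect_spikes(rec, cfg)
        rec2 = SignalRecording(2 * rec.signal, rec.sampling_rate, filtered=True)
        e2 = detect_spikes(rec2, cfg)
        assert np.array_equal(e1.time, e2.time)
        assert np.array_equal(e1.channel, e2.channel)

    def test_negative_polarity_ignores_positive_deflections(self):
        x = np.zeros(20000)
        x[1000:1004] = 50.0
        x[2000:2004] = -50.0
        rec = SignalRecording(x, self.fs, filtered=True)
        events = detect_spikes(rec, SpikeDetectionParams(polarity="negative"))
        assert len(events) == 1
        assert events.amplitude[0] < 0

    def test_recovery_on_synthetic_ground_truth(self):
        # amplitude 8x noise sigma, basal <= 10/s: sensitivity >= 0.95,
        # false positives <= 0.1 events/s/channel
        cfg = MeaSimConfig(
            n_channels=8, duration=10.0, noise_sigma=5.0, spike_amplitude=40.0,
            basal_rate=5.0, burst_rate=0.0, seed=11,
        )
        rec, gt = generate_mea_recording(cfg)
        events = detect_spikes(bandpass_filter(rec))
        true = gt.spike_events
        tp = 0
        for ch in range(cfg.n_channels):
            tt = true.time[true.channel == ch]
            dt = events.time[events.channel == ch]
            for t in tt:
                if dt.size and np.min(np.abs(dt - t)) <= 0.5e-3:
                    tp += 1
        sensitivity = tp / len(true)
        fpr = (len(events) - tp) / (cfg.n_channels * cfg.duration)
        assert sensitivity >= 0.95
        assert fpr <= 0.1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), ns=st.floats(2.0, 6.0))
    def test_refractory_invariant_on_random_inputs(self, seed, ns):
        # per channel, consecutive event times always differ by >= 1 ms
        r = np.random.default_rng(seed)
        x = r.normal(0, 3.0, (2, 4000)) + 8.0 * r.normal(
            0, 1.0, (2, 4000)
        ) * (r.random((2, 4000)) < 0.01)
        rec = SignalRecording(x, 10000.0, filtered=True)
        events = detect_spikes(rec, SpikeDetectionParams(n_s=ns, min_width=0.0))
        for ch in np.unique(events.channel):
            t = np.sort(events.time[events.channel == ch])
            if t.size > 1:
                assert np.all(np.diff(t) >= 1e-3 - 1e-12)


class TestRaster:
    def test_empty_table_gives_all_empty_lists(self):
        events = SpikeEventTable(np.empty(0), np.empty(0))
        r = raster(events, channel_ids=list(range(64)))
        assert len(r) == 64
        assert all(v.size == 0 for v in r.values())

    def test_groups_and_sorts_by_channel(self):
        events = SpikeEventTable(
            np.array([2, 0, 2, 2]), np.array([0.3, 0.1, 0.2, 0.1])
        )
        r = raster(events)
        assert len(r[2]) == 3
        assert np.all(np.diff(r[2]) >= 0)

    def test_round_trip_conserves_every_event(self, filtered_small_recording):
        rec, _, _ = filtered_small_recording
        events = detect_spikes(rec)
        r = raster(events)
        total = sum(v.size for v in r.values())
        assert total == len(events)
        back = np.sort(np.concatenate([v for v in r.values() if v.size]))
        assert np.allclose(back, np.sort(events.time))


class TestHdf5RoundTrip:
    def test_signal_recording_round_trip(self, tmp_path, small_recording):
        rec, _, _ = small_recording
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        back = SignalRecording.from_hdf5(path)
        assert back.sampling_rate == rec.sampling_rate
        assert np.allclose(back.signal, rec.signal.astype(np.float32))
        assert back.channel_ids == rec.channel_ids
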