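"""EMG amplitude and spectral analysis."""

import numpy as np
import pytest

from connscreen.emg import (SignalRecording, amplitude_stats, band_power,
                            cwt_spectrogram, extract_wake, group_band_compare,
                            rms_envelope, welch_psd)
from connscreen.synthetic import EMGSpec, simulate_emg, simulate_emg_group

FS = 1000.0


def recording(x, labels=None):
    return SignalRecording(samples=np.asarray(x, dtype=float), fs=FS,
                           labels=labels)


class TestExtractWake:
    def test_all_wake_is_identity(self, rng):
        rec = recording(rng.normal(size=500))
        out = extract_wake(rec)
        assert np.array_equal(out.samples, rec.samples)
        assert out.segments == [(0, 500)]

    def test_all_sleep_rejected(self, rng):
        rec = recording(rng.normal(size=100), labels=np.zeros(100, dtype=bool))
        with pytest.raises(ValueError, match="wake"):
            extract_wake(rec)

    def test_segments_match_label_runs(self):
        labels = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 1], dtype=bool)
        rec = recording(np.arange(10), labels=labels)
        out = extract_wake(rec)
        assert out.segments == [(0, 2), (2, 5), (5, 6)]
        assert np.array_equal(out.samples, [0, 1, 5, 6, 7, 9])


class TestRMS:
    def test_constant_signal(self):
        assert np.allclose(rms_envelope(recording(np.full(4000, -3.0))), 3.0)

    def test_sine_amplitude_over_whole_cycles(self):
        t = np.arange(int(FS * 4)) / FS
        x = 2.5 * np.sin(2 * np.pi * 10 * t)  # 10 whole cycles per 1 s window
        env = rms_envelope(recording(x), window_s=1.0)
        assert np.allclose(env, 2.5 / np.sqrt(2), atol=1e-10)

    def test_zero_signal(self):
        assert np.allclose(rms_envelope(recording(np.zeros(3000))), 0.0)

    def test_windows_respect_segment_boundaries(self, rng):
        labels = np.zeros(4000, dtype=bool)
        labels[:1500] = True
        labels[2000:2300] = True  # 0.3 s segment: too short for 1 s window
        rec = extract_wake(recording(rng.normal(size=4000), labels=labels))
        env = rms_envelope(rec, window_s=1.0)
        assert len(env) == 1  # only the 1.5 s segment fits one full window

    def test_window_longer_than_all_segments_rejected(self, rng):
        rec = recording(rng.normal(size=100))
        with pytest.raises(ValueError, match="segment"):
            rms_envelope(rec, window_s=1.0)

    def test_quadratic_mean_composition(self, rng):
        x = rng.normal(size=2000)
        whole = np.sqrt(np.mean(x ** 2))
        halves = rms_envelope(recording(x), window_s=1.0)
        assert np.sqrt(np.mean(halves ** 2)) == pytest.approx(whole, abs=1e-12)

    def test_amplitude_stats(self):
        stats = amplitude_stats(np.array([1.0, 2.0, 3.0]))
        assert stats == {"max": 3.0, "mean": 2.0}

    def test_homogeneity_of_stats(self, rng):
        x = rng.normal(size=4000)
        e1 = amplitude_stats(rms_envelope(recording(x)))
        e2 = amplitude_stats(rms_envelope(recording(2 * x)))
        assert e2["max"] == pytest.approx(2 * e1["max"])
        assert e2["mean"] == pytest.approx(2 * e1["mean"])


class TestWelchPSD:
    def test_pure_tone_peaks_at_tone_frequency(self):
        t = np.arange(int(FS * 8)) / FS
        spec = welch_psd(recording(np.sin(2 * np.pi * 100 * t)))
        assert spec.frequencies[np.argmax(spec.density)] == pytest.approx(
            100.0, abs=0.25)

    def test_parseval_white_noise(self, rng):
        x = 1.7 * rng.standard_normal(int(FS * 30))
        spec = welch_psd(recording(x))
        assert spec.total_power == pytest.approx(np.var(x), rel=0.05)

    def test_zero_signal_zero_density(self):
        spec = welch_psd(recording(np.zeros(int(FS * 8))))
        assert np.allclose(spec.density, 0.0)

    def test_offset_invariance_after_detrend(self, rng):
        x = rng.standard_normal(int(FS * 10))
        p1 = welch_psd(recording(x)).total_power
        p2 = welch_psd(recording(x + 42.0)).total_power
        assert p2 == pytest.approx(p1, rel=1e-6)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            welch_psd(recording(np.zeros(100)))


class TestBandPower:
    def test_tone_power_concentrated_in_band(self):
        t = np.arange(int(FS * 10)) / FS
        spec = welch_psd(recording(np.sin(2 * np.pi * 100 * t)))
        assert band_power(spec, 50, 150) >= 0.95 * spec.total_power

    def test_disjoint_bands_partition_total(self, rng):
        spec = welch_psd(recording(rng.standard_normal(int(FS * 10))))
        total = spec.total_power
        parts = (band_power(spec, 0, 20) + band_power(spec, 20, 50)
                 + band_power(spec, 50, 150) + band_power(spec, 150, FS / 2))
        assert parts == pytest.approx(total, abs=1e-9)

    def test_zero_signal_zero_band_power(self):
        spec = welch_psd(recording(np.zeros(int(FS * 8))))
        assert band_power(spec, 20, 150) == 0.0

    def test_band_outside_nyquist_rejected(self, rng):
        spec = welch_psd(recording(rng.standard_normal(int(FS * 8))))
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(spec, 400, 600)


class TestCWT:
    def test_tone_ridge_at_tone_frequency(self):
        t = np.arange(int(FS * 2)) / FS
        rec = recording(np.sin(2 * np.pi * 80 * t))
        freqs, mag = cwt_spectrogram(rec, freqs=np.arange(10, 200, 2.0))
        ridge = freqs[np.argmax(mag[:, mag.shape[1] // 2])]
        assert ridge == pytest.approx(80, abs=2.0)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp
        t = np.arange(int(FS * 4)) / FS
        rec = recording(chirp(t, f0=20, f1=180, t1=4, method="linear"))
        freqs, mag = cwt_spectrogram(rec, freqs=np.arange(5, 250, 2.5))
        for frac in (0.25, 0.5, 0.75):
            col = int(frac * len(t))
            expected = 20 + (180 - 20) * (t[col] / 4)
            ridge = freqs[np.argmax(mag[:, col])]
            assert ridge == pytest.approx(expected, abs=8.0)

    def test_zero_signal_zero_magnitude(self):
        rec = recording(np.zeros(1000))
        _, mag = cwt_spectrogram(rec, freqs=np.arange(10, 100, 5.0))
        assert np.allclose(mag, 0.0)


class TestGroupCompare:
    def test_identical_groups_null(self, rng):
        recs = [recording(rng.normal(size=int(FS * 10))) for _ in range(2)]
        table = group_band_compare(recs, [SignalRecording(r.samples.copy(), FS)
                                          for r in recs], notch=False)
        assert np.allclose(table["t"], 0.0, atol=1e-10)

    def test_swapped_labels_flip_sign(self, rng):
        ga = [recording(rng.normal(size=int(FS * 10))) for _ in range(3)]
        gb = [recording(rng.normal(size=int(FS * 10))) for _ in range(3)]
        t1 = group_band_compare(ga, gb, notch=False)["t"]
        t2 = group_band_compare(gb, ga, notch=False)["t"]
        assert np.allclose(t1, -t2, atol=1e-10)

    def test_doubled_gain_detected_in_target_band(self):
        spec = EMGSpec(duration_s=40.0, seed=5)
        ga = simulate_emg_group(spec, 6, "A",
                                gain_scale={(50.0, 150.0): 2.0}, seed=21)
        gb = simulate_emg_group(spec, 5, "B", seed=22)
        table = group_band_compare(ga, gb).set_index(["band_lo_hz",
                                                      "band_hi_hz"])
        assert table.loc[(50.0, 150.0), "p"] < 0.05
        assert table.loc[(50.0, 150.0), "ratio_a_over_b"] == pytest.approx(
            4.0, rel=0.5)
        assert table.loc[(20.0, 50.0), "ratio_a_over_b"] == pytest.approx(
            1.0, abs=0.5)


class TestSimulateEMG:
    def test_reproducible(self):
        spec = EMGSpec(duration_s=5.0, seed=9)
        r1, r2 = simulate_emg(spec), simulate_emg(spec)
        assert np.array_equal(r1.samples, r2.samples)

    def test_sample_count(self):
        rec = simulate_emg(EMGSpec(duration_s=300.0, seed=1))
        assert rec.samples.size == 300_000

    def test_all_zero_gains_and_mains_give_silence(self):
        spec = EMGSpec(duration_s=5.0, mains_amp=0.0,
                       band_gains=(((20.0, 50.0), 0.0), ((50.0, 150.0), 0.0)),
                       seed=3)
        assert np.allclose(simulate_emg(spec).samples, 0.0)

    def test_duration_too_short_for_lowest_band_rejected(self):
        with pytest.raises(ValueError, match="2 cycles"):
            EMGSpec(duration_s=1.0, band_gains=(((1.0, 20.0), 1.0),))
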