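import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal.windows import blackmanharris as scipy_bh

from wingbeat import (
    ExtractionConfig,
    SignalTrack,
    apply_window,
    autocorr_f0,
    blackman_harris,
    extract_features,
    fft_spectrum,
    pick_components,
    run_detection,
    zero_pad_to_resolution,
)
from wingbeat import DetectionConfig

from .conftest import FS, make_burst_track


def brute_force_autocorr_lag(x, lag_min, lag_max):
    best, best_lag = -np.inf, lag_min
    for l in range(lag_min, lag_max + 1):
        r = float(np.sum(x[l:] * x[: len(x) - l]))
        if r > best:
            best, best_lag = r, l
    return best_lag


class TestBlackmanHarris:
    def test_edge_value(self):
        w = blackman_harris(101)
        assert w[0] == pytest.approx(0.35875 - 0.48829 + 0.14128 - 0.01168, abs=1e-12)
        assert w[0] == pytest.approx(6e-5, abs=1e-6)

    def test_center_value(self):
        w = blackman_harris(101)  # odd length: exact center sample
        assert w[50] == pytest.approx(0.35875 + 0.48829 + 0.14128 + 0.01168, abs=1e-12)
        assert w[50] == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 4000))
    def test_symmetry(self, n):
        w = blackman_harris(n)
        assert np.allclose(w, w[::-1], atol=1e-12)

    def test_matches_scipy_reference(self):
        for n in (64, 257, 1000):
            assert np.allclose(blackman_harris(n), scipy_bh(n, sym=True), atol=1e-12)

    def test_reduces_leakage_sidelobes(self):
        # off-bin tone: windowed spectrum has lower far sidelobes than unwindowed
        n = int(0.3 * FS)
        t = np.arange(n) / FS
        tone = np.sin(2 * np.pi * 150.4 * t)
        raw = np.abs(np.fft.rfft(zero_pad_to_resolution(tone, FS)))
        win = np.abs(np.fft.rfft(zero_pad_to_resolution(apply_window(tone), FS)))
        far = slice(400, 1000)  # bins well away from the 150 Hz mainlobe
        assert win[far].max() / win.max() < raw[far].max() / raw.max()


class TestZeroPad:
    def test_pads_to_whole_second(self):
        wave = np.ones(int(0.3 * FS))
        assert len(zero_pad_to_resolution(wave, FS)) == int(FS)

    def test_long_events_pad_to_next_second(self):
        wave = np.ones(int(1.4 * FS))
        assert len(zero_pad_to_resolution(wave, FS)) == int(2 * FS)

    def test_energy_preserved(self, rng):
        wave = rng.uniform(-1, 1, int(0.25 * FS))
        padded = zero_pad_to_resolution(wave, FS)
        assert np.sum(padded**2) == pytest.approx(np.sum(wave**2), rel=1e-12)


class TestAutocorrF0:
    def test_pure_tone_exact_lag(self):
        t = np.arange(int(0.3 * FS)) / FS
        x = apply_window(np.sin(2 * np.pi * 100 * t))
        t0, f0 = autocorr_f0(x, FS)
        assert t0 == pytest.approx(192 / FS)
        assert f0 == pytest.approx(100.0)

    def test_period_to_frequency_reciprocal(self):
        # 9.12 ms fundamental period <-> 109.65 Hz: fs chosen so the lag is integral
        fs = 12500.0
        t = np.arange(int(0.4 * fs)) / fs
        x = apply_window(np.sin(2 * np.pi * t / 0.00912))
        t0, f0 = autocorr_f0(x, fs)
        assert t0 == pytest.approx(0.00912)
        assert round(f0, 2) == 109.65

    def test_matches_brute_force_lag_scan(self, rng):
        t = np.arange(int(0.25 * FS)) / FS
        x = apply_window(
            np.sin(2 * np.pi * 137 * t) + 0.4 * np.sin(2 * np.pi * 274 * t)
            + 0.02 * rng.normal(size=len(t))
        )
        t0, _ = autocorr_f0(x, FS)
        lag = brute_force_autocorr_lag(x, int(np.ceil(FS / 500)), int(FS // 70))
        assert int(round(t0 * FS)) == lag

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty lag range|band"):
            autocorr_f0(np.ones(10), FS, search_band=(70.0, 500.0))


class TestFftSpectrum:
    def test_tone_lands_on_its_bin(self):
        t = np.arange(int(FS)) / FS
        freqs, mags = fft_spectrum(np.sin(2 * np.pi * 150 * t), FS)
        assert freqs[np.argmax(mags)] == pytest.approx(150.0)

    def test_parseval(self, rng):
        x = rng.uniform(-1, 1, int(FS))
        spec = np.fft.rfft(x)
        # account for rfft's one-sided folding
        energy = (np.abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:-1]) ** 2)
                  + np.abs(spec[-1]) ** 2) / len(x)
        assert energy == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_linearity_before_magnitude(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert np.allclose(
            np.fft.rfft(x + y), np.fft.rfft(x) + np.fft.rfft(y), atol=1e-9
        )


class TestPickComponents:
    @staticmethod
    def _harmonic_spectrum(f0=110.0, amps=(1.0, 0.45, 0.25, 0.12, 0.06)):
        t = np.arange(int(0.4 * FS)) / FS
        x = sum(a * np.sin(2 * np.pi * f0 * (k + 1) * t) for k, a in enumerate(amps))
        return fft_spectrum(zero_pad_to_resolution(apply_window(x), FS), FS)

    def test_five_harmonics_recovered(self):
        freqs, mags = self._harmonic_spectrum()
        comp = pick_components(freqs, mags)
        assert comp.f0_fft == pytest.approx(110.0, abs=1.0)
        assert np.allclose(comp.freqs, [220, 330, 440, 550], atol=1.0)
        assert comp.valid.all()

    def test_pure_tone_flags_components_invalid(self):
        t = np.arange(int(0.4 * FS)) / FS
        freqs, mags = fft_spectrum(
            zero_pad_to_resolution(apply_window(np.sin(2 * np.pi * 150 * t)), FS), FS
        )
        comp = pick_components(freqs, mags)
        assert comp.f0_fft == pytest.approx(150.0, abs=1.0)
        assert not comp.valid.any()

    def test_dominant_second_harmonic_gives_octave_error(self):
        # documented FFT failure mode: the picked "fundamental" is 2 x F0
        freqs, mags = self._harmonic_spectrum(amps=(0.4, 1.0, 0.2, 0.1, 0.05))
        comp = pick_components(freqs, mags)
        assert comp.f0_fft == pytest.approx(220.0, abs=1.0)

    def test_magnitudes_sorted_with_frequencies(self):
        freqs, mags = self._harmonic_spectrum()
        comp = pick_components(freqs, mags)
        assert np.all(np.diff(comp.freqs) > 0)
        assert comp.m0 >= comp.mags.max()


class TestExtractFeatures:
    def test_ground_truth_recovery_high_snr(self):
        track = make_burst_track(f0=160.0, burst_s=0.3, noise_sd=0.002)
        ev = run_detection(track, DetectionConfig(threshold=0.02))[0]
        comp, vec = extract_features(ev)
        assert vec.f0_aut == pytest.approx(160.0, abs=2.0)
        assert vec.f0_fft == pytest.approx(160.0, abs=2.0)
        # pure tone: no genuine 2nd component, so f1 - f0 is unavailable
        assert np.isnan(vec.f1_minus_f0)

    def test_harmonic_event_all_three_estimates_agree(self, rng):
        from wingbeat import SpeciesSynthParams, generate_event

        params = SpeciesSynthParams("x", 160.0, 0.0, inharmonicity_sd=0.0)
        wave, _ = generate_event(params, FS, rng)
        comp, vec = extract_features(wave, FS)
        for est in (vec.f0_aut, vec.f0_fft, vec.f1_minus_f0):
            assert est == pytest.approx(160.0, abs=2.0)

    def test_magnitude_ratio_recovered(self, rng):
        from wingbeat import SpeciesSynthParams, generate_event

        params = SpeciesSynthParams(
            "x", 120.0, 0.0, inharmonicity_sd=0.0, mag_ratio_mean=2.26
        )
        wave, _ = generate_event(params, FS, rng)
        _, vec = extract_features(wave, FS)
        assert vec.mag_ratio_01 == pytest.approx(2.26, rel=0.10)

    def test_amplitude_scale_invariance(self, rng):
        from wingbeat import SpeciesSynthParams, generate_event

        params = SpeciesSynthParams("x", 130.0, 0.0)
        wave, _ = generate_event(params, FS, rng)
        _, v1 = extract_features(wave, FS)
        _, v2 = extract_features(0.05 * wave, FS)
        assert v1.f0_aut == v2.f0_aut
        assert v1.f0_fft == v2.f0_fft
        assert v1.mag_ratio_01 == pytest.approx(v2.mag_ratio_01, rel=1e-9)

    def test_subharmonic_content_halves_autocorr_estimate(self):
        # documented autocorrelation failure mode: a weak component at half the
        # wing-beat frequency makes the full pattern repeat at twice the period
        t = np.arange(int(0.4 * FS)) / FS
        x = (np.sin(2 * np.pi * 160 * t) + 0.6 * np.sin(2 * np.pi * 320 * t)
             + 0.3 * np.sin(2 * np.pi * 80 * t))
        _, vec = extract_features(x, FS)
        assert vec.f0_aut == pytest.approx(80.0, abs=2.0)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_features(np.array([]), FS)
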