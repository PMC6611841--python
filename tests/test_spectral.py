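"""Amplitude spectra, low-frequency detrending and band-peak extraction."""

import numpy as np
import pytest

from aqueductflow import (
    GradientWindow,
    SpectralConfig,
    amplitude_spectrum,
    analyze_window,
    extract_band_peaks,
    remove_lowfreq_trend,
)

FS = 200.0
N = int(360 * FS)
T = np.arange(N) / FS
DF = 1.0 / 360.0  # bin width


def _window(x, state="unknown"):
    return GradientWindow(
        dicp=np.asarray(x, dtype=float),
        sampling_rate=FS,
        start_offset=0.0,
        accepted=True,
        raw_difference_range=0.0,
        state=state,
        patient_id="t",
        window_index=0,
    )


class TestAmplitudeSpectrum:
    def test_pure_sinusoid_peak_equals_amplitude(self):
        # 1.1 Hz = 396 whole periods in 360 s: exactly on a bin
        w = _window(1.5 * np.sin(2 * np.pi * 1.1 * T))
        freqs, amps = amplitude_spectrum(w)
        k = int(np.argmax(amps))
        assert freqs[k] == pytest.approx(1.1, abs=1e-9)
        assert amps[k] == pytest.approx(1.5, rel=1e-9)
        others = np.delete(amps, k)
        assert np.max(others) < 1e-6 * amps[k]

    def test_zero_signal_gives_zero_spectrum(self):
        _, amps = amplitude_spectrum(_window(np.zeros(N)))
        assert np.all(amps == 0.0)

    def test_two_sinusoids_give_two_independent_peaks(self):
        x = 1.5 * np.sin(2 * np.pi * 1.1 * T) + 0.5 * np.sin(2 * np.pi * 0.25 * T)
        freqs, amps = amplitude_spectrum(_window(x))
        assert amps[np.argmin(np.abs(freqs - 1.1))] == pytest.approx(1.5, rel=1e-9)
        assert amps[np.argmin(np.abs(freqs - 0.25))] == pytest.approx(0.5, rel=1e-9)

    def test_lowpass_zeroes_above_cutoff(self):
        x = np.sin(2 * np.pi * 20.0 * T)  # above the 15 Hz cutoff
        freqs, amps = amplitude_spectrum(_window(x))
        assert np.all(amps[freqs > 15.0] == 0.0)
        assert np.max(amps) < 1e-9

    def test_parseval_energy_matches_variance(self):
        rng = np.random.default_rng(11)
        # band-limited random signal well below the cutoff
        x = sum(
            a * np.sin(2 * np.pi * f * T + p)
            for a, f, p in zip(rng.uniform(0.2, 2, 8), rng.uniform(0.2, 5, 8), rng.uniform(0, 6, 8))
        )
        x = x - x.mean()
        _, amps = amplitude_spectrum(_window(x))
        spectral_power = 0.5 * np.sum(amps[1:] ** 2)
        assert spectral_power == pytest.approx(np.var(x), rel=0.01)


class TestLowFreqTrend:
    def test_no_low_frequency_energy_is_near_identity(self):
        w = _window(1.5 * np.sin(2 * np.pi * 1.1 * T))
        freqs, amps = amplitude_spectrum(w)
        _, corrected = remove_lowfreq_trend(freqs, amps)
        k = int(np.argmin(np.abs(freqs - 1.1)))
        assert corrected[k] == pytest.approx(amps[k], rel=1e-6)

    def test_exponential_floor_removed_and_peaks_preserved(self):
        freqs = np.arange(0, 15.0, DF)
        floor = 2.0 * np.exp(-5.0 * freqs)
        amps = floor.copy()
        kc = int(round(1.1 / DF))
        kr = int(round(0.25 / DF))
        amps[kc] += 1.5
        amps[kr] += 0.5
        _, corrected = remove_lowfreq_trend(freqs, amps)
        assert corrected[kc] == pytest.approx(1.5, rel=0.05)
        assert corrected[kr] == pytest.approx(0.5, rel=0.05)
        low = (freqs > 0) & (freqs < 0.1)
        assert np.sum(corrected[low]) < 0.1 * np.sum(amps[low])

    def test_all_zero_spectrum_passes_through(self):
        freqs = np.arange(0, 15.0, DF)
        _, corrected = remove_lowfreq_trend(freqs, np.zeros_like(freqs))
        assert np.all(corrected == 0.0)


class TestBandPeaks:
    def test_recovers_synthetic_components(self):
        x = 1.5 * np.sin(2 * np.pi * 1.1 * T) + 0.5 * np.sin(2 * np.pi * 0.25 * T)
        s = analyze_window(_window(x))
        assert s.f0_cardiac == pytest.approx(1.1, abs=DF)
        assert s.a0_cardiac == pytest.approx(1.5, rel=0.05)
        assert s.f1_resp == pytest.approx(0.25, abs=DF)
        assert s.a1_resp == pytest.approx(0.5, rel=0.05)

    def test_empty_respiratory_band_flagged(self):
        x = 1.5 * np.sin(2 * np.pi * 1.1 * T)
        s = analyze_window(_window(x))
        assert s.a1_resp == 0.0
        assert not s.resp_found
        assert s.cardiac_found

    def test_calibration_scales_amplitudes_not_frequencies(self):
        x = 1.5 * np.sin(2 * np.pi * 1.1 * T) + 0.5 * np.sin(2 * np.pi * 0.25 * T)
        base = analyze_window(_window(x), SpectralConfig(calibration_C=1.0))
        cal = analyze_window(_window(x), SpectralConfig(calibration_C=7.0))
        assert cal.a0_cardiac == pytest.approx(7 * base.a0_cardiac, rel=1e-9)
        assert cal.a1_resp == pytest.approx(7 * base.a1_resp, rel=1e-9)
        assert cal.f0_cardiac == base.f0_cardiac
        # C cancels in the cardiac/respiratory amplitude ratio
        assert cal.a0_cardiac / cal.a1_resp == pytest.approx(
            base.a0_cardiac / base.a1_resp, rel=1e-9
        )

    def test_scale_equivariance(self):
        x = 1.5 * np.sin(2 * np.pi * 1.1 * T) + 0.5 * np.sin(2 * np.pi * 0.25 * T)
        s1 = analyze_window(_window(x))
        s3 = analyze_window(_window(3.0 * x))
        assert s3.a0_cardiac == pytest.approx(3 * s1.a0_cardiac, rel=1e-9)
        assert s3.a1_resp == pytest.approx(3 * s1.a1_resp, rel=1e-9)

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.arange(0, 2.0, DF)
        amps = np.zeros_like(freqs)
        k1 = int(round(0.9 / DF))
        k2 = int(round(1.2 / DF))
        amps[k1] = amps[k2] = 1.0
        s = extract_band_peaks(freqs, amps)
        assert s.f0_cardiac == pytest.approx(freqs[k1])


class TestParameterRecovery:
    def test_noisy_windows_recover_amplitudes_and_frequencies(self):
        """Seeded ensemble: median amplitude error < 5%, frequency within one
        bin, at in-band SNR of 5."""
        rng = np.random.default_rng(1234)
        amp_errs, freq_ok = [], []
        n_trials = 50
        for _ in range(n_trials):
            a_c = rng.uniform(0.8, 3.0)
            a_r = rng.uniform(0.3, 0.9)
            f_c = round(rng.uniform(0.75, 1.55) / DF) * DF
            f_r = round(rng.uniform(0.17, 0.38) / DF) * DF
            noise_sd = a_r / 5.0  # SNR 5 on the weaker component
            x = (
                a_c * np.sin(2 * np.pi * f_c * T)
                + a_r * np.sin(2 * np.pi * f_r * T)
                + rng.normal(0.0, noise_sd, N)
            )
            s = analyze_window(_window(x))
            amp_errs.append(abs(s.a0_cardiac - a_c) / a_c)
            amp_errs.append(abs(s.a1_resp - a_r) / a_r)
            freq_ok.append(abs(s.f0_cardiac - f_c) <= DF + 1e-12)
            freq_ok.append(abs(s.f1_resp - f_r) <= DF + 1e-12)
        assert np.median(amp_errs) < 0.05
        assert all(freq_ok)
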