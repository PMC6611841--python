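"""Spectral extraction of cardiac and respiratory gradient components.

Each accepted 6-minute dICP window is Fourier transformed and reduced to
two (frequency, amplitude) pairs: the cardiac peak in 0.7–1.6 Hz (42–96
beats/min) and the respiratory peak in 0.15–0.4 Hz (9–24 breaths/min).
The spectrum is a calibrated single-sided amplitude spectrum: a stationary
sinusoid of amplitude a appears as a peak of height a, so synthetic
parameter recovery is exact with calibration C = 1. Pipelines matching the
original clinical processing can set C = 7, the heuristic factor that maps
that processing's spectral peak back to time-domain amplitude; C rescales
both bands equally and cancels in every cardiac/respiratory ratio.

Head movement and posture drift put energy below 0.1 Hz whose spectral
skirt can leak into the respiratory band; it is removed by fitting a
decreasing exponential A·exp(−b·f) to the sub-cardiac spectrum (excluding
the respiratory band) and subtracting it, clamping at zero. Components
above a 15 Hz cutoff are zeroed before peak extraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recordings import GradientWindow

__all__ = [
    "SpectralConfig",
    "SpectrumSummary",
    "amplitude_spectrum",
    "remove_lowfreq_trend",
    "extract_band_peaks",
    "analyze_window",
    "spectrum_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectralConfig:
    lowpass_cutoff: float = 15.0  # Hz
    cardiac_band: tuple[float, float] = (0.7, 1.6)  # Hz
    resp_band: tuple[float, float] = (0.15, 0.4)  # Hz
    lowfreq_threshold: float = 0.1  # Hz
    calibration_C: float = 1.0  # clinical-processing value: 7

    def __post_init__(self) -> None:
        if self.resp_band[1] >= self.cardiac_band[0]:
            raise ValueError("cardiac and respiratory bands must be disjoint")
        if self.lowpass_cutoff <= self.cardiac_band[1]:
            raise ValueError("low-pass cutoff must lie above the cardiac band")
        if self.calibration_C <= 0:
            raise ValueError("calibration_C must be positive")


@dataclass(frozen=True)
class SpectrumSummary:
    """Cardiac and respiratory (frequency, amplitude) pairs for one window."""

    f0_cardiac: float  # Hz
    a0_cardiac: float  # mmHg/m (calibrated)
    f1_resp: float  # Hz
    a1_resp: float  # mmHg/m (calibrated)
    calibration_C: float = 1.0
    cardiac_found: bool = True
    resp_found: bool = True
    window_ref: str = ""
    state: str = "unknown"


def amplitude_spectrum(window: GradientWindow, config: SpectralConfig | None = None):
    """Single-sided amplitude spectrum of the window's dICP.

    Normalised so a pure sinusoid of amplitude a with an integer number of
    periods in the window yields a peak of exactly a at its bin. Frequency
    resolution is 1/duration (1/360 Hz for standard windows). Bins above
    the low-pass cutoff are zeroed — the cutoff acts on the spectrum, not
    as a time-domain filter.

    Returns
    -------
    (freqs, amps) : arrays of bin frequencies (Hz) and amplitudes (mmHg/m).
    """
    config = config or SpectralConfig()
    x = np.asarray(window.dicp, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty window")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / window.sampling_rate)
    amps = np.abs(spec) / n
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not doubled
    amps[freqs > config.lowpass_cutoff] = 0.0
    return freqs, amps


def remove_lowfreq_trend(
    freqs: np.ndarray, amps: np.ndarray, config: SpectralConfig | None = None
):
    """Subtract a fitted decreasing exponential A·exp(−b·f) from the spectrum.

    The fit is a linear least-squares on log-amplitude over bins with
    0 < f < cardiac-band start, excluding the respiratory band (so genuine
    respiratory peaks do not inflate the trend). A ≥ 0 holds by
    construction; b < 0 (non-decreasing fit) is clamped to 0. Results are
    clamped at zero after subtraction. Degenerate spectra (fewer than two
    usable bins) pass through unchanged with a warning.
    """
    config = config or SpectralConfig()
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    fit_mask = (
        (freqs > 0)
        & (freqs < config.cardiac_band[0])
        & ~((freqs >= config.resp_band[0]) & (freqs <= config.resp_band[1]))
        & (amps > 0)
    )
    if fit_mask.sum() < 2:
        logger.warning("low-frequency trend fit degenerate; spectrum left unchanged")
        return freqs, amps.copy()
    f_fit = freqs[fit_mask]
    log_a = np.log(amps[fit_mask])
    slope, intercept = np.polyfit(f_fit, log_a, 1)
    b = max(-slope, 0.0)
    A = np.exp(intercept)
    corrected = amps - A * np.exp(-b * freqs)
    return freqs, np.clip(corrected, 0.0, None)


def _band_peak(freqs, amps, band, floor):
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return float("nan"), 0.0, False
    idx = np.flatnonzero(mask)
    # argmax returns the first (lowest-frequency) maximal bin: tie-break low
    best = idx[int(np.argmax(amps[idx]))]
    amp = float(amps[best])
    if amp <= floor:  # numerically zero (round-off leakage only)
        return float(freqs[best]), 0.0, False
    return float(freqs[best]), amp, True


def extract_band_peaks(
    freqs: np.ndarray,
    amps: np.ndarray,
    config: SpectralConfig | None = None,
    window_ref: str = "",
    state: str = "unknown",
) -> SpectrumSummary:
    """Locate the cardiac and respiratory band maxima and calibrate them.

    Amplitudes are multiplied by ``config.calibration_C``. A band whose
    maximum is zero is reported with amplitude 0 and its ``*_found`` flag
    cleared.
    """
    config = config or SpectralConfig()
    floor = 1e-12 * float(np.max(amps)) if np.any(amps > 0) else 0.0
    f0, a0, c_found = _band_peak(freqs, amps, config.cardiac_band, floor)
    f1, a1, r_found = _band_peak(freqs, amps, config.resp_band, floor)
    return SpectrumSummary(
        f0_cardiac=f0,
        a0_cardiac=a0 * config.calibration_C,
        f1_resp=f1,
        a1_resp=a1 * config.calibration_C,
        calibration_C=config.calibration_C,
        cardiac_found=c_found,
        resp_found=r_found,
        window_ref=window_ref,
        state=state,
    )


def analyze_window(window: GradientWindow, config: SpectralConfig | None = None) -> SpectrumSummary:
    """Full per-window chain: spectrum → low-frequency correction → band peaks."""
    config = config or SpectralConfig()
    freqs, amps = amplitude_spectrum(window, config)
    freqs, amps = remove_lowfreq_trend(freqs, amps, config)
    ref = f"{window.patient_id}:{window.window_index}"
    return extract_band_peaks(freqs, amps, config, window_ref=ref, state=window.state)


def spectrum_table(summaries: list[SpectrumSummary]) -> pd.DataFrame:
    """Per-window summary rows (the pipeline's analogue of a per-patient
    gradient-statistics table)."""
    return pd.DataFrame(
        {
            "window_ref": [s.window_ref for s in summaries],
            "f0_cardiac_Hz": [s.f0_cardiac for s in summaries],
            "a0_cardiac_mmHg_per_m": [s.a0_cardiac for s in summaries],
            "f1_resp_Hz": [s.f1_resp for s in summaries],
            "a1_resp_mmHg_per_m": [s.a1_resp for s in summaries],
            "state": [s.state for s in summaries],
        }
    )
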