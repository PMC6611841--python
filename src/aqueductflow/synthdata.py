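"""Synthetic dual-sensor intracranial-pressure recordings.

Clinical overnight ICP recordings from paired sensors are not publicly
available, so this module generates signal-structure-matched stand-ins: two
co-sampled channels sharing a large common-mode pulsatile ICP (cardiac
amplitude ~4–5 mmHg) with a small differential signal — a cardiac sinusoid
(0.7–1.6 Hz), a respiratory sinusoid (0.15–0.4 Hz), slow drift (<0.1 Hz),
optional step artifacts (posture changes) and white sensor noise. The
generating components are attached as ground truth so every downstream
stage (windowing, spectral extraction, flow modelling) can be validated
against known parameters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recordings import ICPRecording

__all__ = ["SyntheticSpec", "GroundTruth", "generate_recording", "write_recording", "read_recording"]

CARDIAC_BAND = (0.7, 1.6)
RESP_BAND = (0.15, 0.4)

#: Respiratory fraction of the common-mode cardiac amplitude. The common
#: mode emulates raw ICP, which is cardiac-dominated; the respiratory
#: modulation is smaller.
COMMON_MODE_RESP_FRACTION = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Amplitude conventions: ``common_mode_amplitude`` is the cardiac ICP
    pulse amplitude in mmHg, identical in both channels (it cancels in the
    difference). Gradient amplitudes are in mmHg/m and enter the second
    channel multiplied by the sensor separation ``sensor_distance_L``.
    """

    duration: float = 3600.0  # s
    sampling_rate: float = 200.0  # Hz
    sensor_distance_L: float = 0.06  # m
    common_mode_amplitude: float = 4.5  # mmHg
    cardiac_grad_amplitude: float = 1.46  # mmHg/m
    cardiac_freq: float = 62.0 / 60.0  # Hz
    resp_grad_amplitude: float = 0.52  # mmHg/m
    resp_freq: float = 15.0 / 60.0  # Hz
    drift_amplitude: float = 0.0  # mmHg
    drift_freq: float = 0.02  # Hz
    noise_sd: float = 0.0  # mmHg
    artifact_times: tuple[float, ...] = ()
    artifact_steps: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        amps = {
            "common_mode_amplitude": self.common_mode_amplitude,
            "cardiac_grad_amplitude": self.cardiac_grad_amplitude,
            "resp_grad_amplitude": self.resp_grad_amplitude,
            "drift_amplitude": self.drift_amplitude,
            "noise_sd": self.noise_sd,
        }
        for name, v in amps.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.sensor_distance_L <= 0:
            raise ValueError("sensor_distance_L must be positive")
        if not CARDIAC_BAND[0] <= self.cardiac_freq <= CARDIAC_BAND[1]:
            raise ValueError(
                f"cardiac_freq {self.cardiac_freq} outside physiological band {CARDIAC_BAND}"
            )
        if not RESP_BAND[0] <= self.resp_freq <= RESP_BAND[1]:
            raise ValueError(
                f"resp_freq {self.resp_freq} outside physiological band {RESP_BAND}"
            )
        if self.drift_freq >= 0.1:
            raise ValueError("drift_freq must be below 0.1 Hz")
        f_max = max(self.cardiac_freq, self.resp_freq, self.drift_freq)
        if self.sampling_rate <= 2 * f_max:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz does not resolve {f_max} Hz"
            )
        if len(self.artifact_times) != len(self.artifact_steps):
            raise ValueError("artifact_times and artifact_steps must have equal length")


@dataclass(frozen=True)
class GroundTruth:
    """Generating components of the differential signal (gradient units,
    mmHg/m, except the step artifacts which are pressures in mmHg)."""

    cardiac_amplitude: float
    cardiac_freq: float
    resp_amplitude: float
    resp_freq: float
    drift_amplitude: float
    drift_freq: float
    noise_sd: float
    artifact_times: tuple[float, ...] = ()
    artifact_steps: tuple[float, ...] = ()


def _time_grid(spec: SyntheticSpec) -> np.ndarray:
    n = int(round(spec.duration * spec.sampling_rate))
    return np.arange(n) / spec.sampling_rate


def generate_recording(
    spec: SyntheticSpec, patient_id: str = "synthetic", start_clock: str = "22:00:00"
) -> ICPRecording:
    """Generate a two-channel recording with attached ground truth.

    Channel IV (ventricular) carries the common mode plus its own noise;
    channel SD (subdural) adds L × (cardiac + respiratory + drift gradient
    waveforms) and any step artifacts, plus independent noise. Deterministic
    for a fixed ``spec.seed``.
    """
    t = _time_grid(spec)
    two_pi = 2 * np.pi
    common = spec.common_mode_amplitude * (
        np.sin(two_pi * spec.cardiac_freq * t)
        + COMMON_MODE_RESP_FRACTION * np.sin(two_pi * spec.resp_freq * t)
    )

    L = spec.sensor_distance_L
    differential = L * (
        spec.cardiac_grad_amplitude * np.sin(two_pi * spec.cardiac_freq * t)
        + spec.resp_grad_amplitude * np.sin(two_pi * spec.resp_freq * t)
        + spec.drift_amplitude * np.sin(two_pi * spec.drift_freq * t)
    )
    for t_step, step in zip(spec.artifact_times, spec.artifact_steps):
        differential = differential + np.where(t >= t_step, step, 0.0)

    rng = np.random.default_rng(spec.seed)
    noise_iv = rng.normal(0.0, spec.noise_sd, t.size) if spec.noise_sd > 0 else 0.0
    noise_sd_ch = rng.normal(0.0, spec.noise_sd, t.size) if spec.noise_sd > 0 else 0.0

    icp_iv = common + noise_iv
    icp_sd = common + differential + noise_sd_ch

    truth = GroundTruth(
        cardiac_amplitude=spec.cardiac_grad_amplitude,
        cardiac_freq=spec.cardiac_freq,
        resp_amplitude=spec.resp_grad_amplitude,
        resp_freq=spec.resp_freq,
        drift_amplitude=spec.drift_amplitude,
        drift_freq=spec.drift_freq,
        noise_sd=spec.noise_sd,
        artifact_times=spec.artifact_times,
        artifact_steps=spec.artifact_steps,
    )
    return ICPRecording(
        time=t,
        icp_iv=np.asarray(icp_iv, dtype=float) + np.zeros_like(t),
        icp_sd_or_par=np.asarray(icp_sd, dtype=float),
        sampling_rate=spec.sampling_rate,
        sensor_distance_L=L,
        start_clock=start_clock,
        patient_id=patient_id,
        ground_truth=truth,
    )


def write_recording(rec: ICPRecording, csv_path: str | Path) -> Path:
    """Write channels as CSV (time_s, icp_iv_mmHg, icp_sd_mmHg) plus a YAML
    side-car ``<stem>.meta.yaml`` with L, start clock, patient id and any
    ground truth."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"time_s": rec.time, "icp_iv_mmHg": rec.icp_iv, "icp_sd_mmHg": rec.icp_sd_or_par}
    )
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "patient_id": rec.patient_id,
        "sensor_distance_L_m": float(rec.sensor_distance_L),
        "sampling_rate_Hz": float(rec.sampling_rate),
        "start_clock": rec.start_clock,
    }
    if rec.ground_truth is not None:
        gt = rec.ground_truth
        meta["ground_truth"] = {
            "cardiac_amplitude_mmHg_per_m": gt.cardiac_amplitude,
            "cardiac_freq_Hz": gt.cardiac_freq,
            "resp_amplitude_mmHg_per_m": gt.resp_amplitude,
            "resp_freq_Hz": gt.resp_freq,
            "drift_amplitude_mmHg": gt.drift_amplitude,
            "drift_freq_Hz": gt.drift_freq,
            "noise_sd_mmHg": gt.noise_sd,
            "artifact_times_s": list(gt.artifact_times),
            "artifact_steps_mmHg": list(gt.artifact_steps),
        }
    meta_path = csv_path.with_suffix("").with_suffix(".meta.yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return csv_path


def read_recording(csv_path: str | Path) -> ICPRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix("").with_suffix(".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    truth = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        truth = GroundTruth(
            cardiac_amplitude=g["cardiac_amplitude_mmHg_per_m"],
            cardiac_freq=g["cardiac_freq_Hz"],
            resp_amplitude=g["resp_amplitude_mmHg_per_m"],
            resp_freq=g["resp_freq_Hz"],
            drift_amplitude=g["drift_amplitude_mmHg"],
            drift_freq=g["drift_freq_Hz"],
            noise_sd=g["noise_sd_mmHg"],
            artifact_times=tuple(g.get("artifact_times_s", ())),
            artifact_steps=tuple(g.get("artifact_steps_mmHg", ())),
        )
    time = df["time_s"].to_numpy()
    fs = meta.get("sampling_rate_Hz")
    if fs is None:
        fs = 1.0 / np.median(np.diff(time))
    return ICPRecording(
        time=time,
        icp_iv=df["icp_iv_mmHg"].to_numpy(),
        icp_sd_or_par=df["icp_sd_mmHg"].to_numpy(),
        sampling_rate=float(fs),
        sensor_distance_L=float(meta.get("sensor_distance_L_m", np.nan)),
        start_clock=meta.get("start_clock"),
        patient_id=meta.get("patient_id", csv_path.stem),
        ground_truth=truth,
    )
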