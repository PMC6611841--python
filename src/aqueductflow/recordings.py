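"""Dual-sensor ICP recordings: differential gradient, window vetting,
circadian labelling.

The differential ICP (dICP) is the pressure difference between the two
sensors divided by their separation L, in mmHg/m — the proxy for the axial
pressure gradient driving aqueductal CSF flow. Recordings are cut into
consecutive non-overlapping 6-minute windows (the typical duration of a
cardiac-gated PC-MRI acquisition). A window is accepted only if the raw
pressure difference varies by strictly less than 2 mmHg over the window —
larger excursions indicate posture changes or sensor artifacts. Accepted
windows are mean-shifted to zero, removing hydrostatic/static offsets
(body position was not recorded in the source protocol), and labelled
sleeping when they start between midnight and 06:00.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ICPRecording",
    "GradientWindow",
    "WINDOW_DURATION_S",
    "ACCEPTANCE_THRESHOLD_MMHG",
    "SLEEP_START",
    "SLEEP_END",
    "compute_dicp",
    "extract_windows",
    "categorize_state",
    "window_index_table",
]

WINDOW_DURATION_S = 360.0
ACCEPTANCE_THRESHOLD_MMHG = 2.0
SLEEP_START = _dt.time(0, 0)
SLEEP_END = _dt.time(6, 0)  # half-open: 06:00:00 itself is awake


@dataclass
class ICPRecording:
    """Two co-sampled ICP channels on a uniform time grid.

    ``icp_sd_or_par`` is the subdural channel for most patients and the
    parenchymal channel for the others; both are handled identically.
    ``start_clock`` is the wall-clock time of sample zero ("HH:MM:SS"),
    used only for sleep/awake labelling.
    """

    time: np.ndarray  # s from start
    icp_iv: np.ndarray  # mmHg
    icp_sd_or_par: np.ndarray  # mmHg
    sampling_rate: float  # Hz
    sensor_distance_L: float  # m
    start_clock: Optional[str] = None
    patient_id: str = ""
    ground_truth: object = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.icp_iv = np.asarray(self.icp_iv, dtype=float)
        self.icp_sd_or_par = np.asarray(self.icp_sd_or_par, dtype=float)
        if not (len(self.time) == len(self.icp_iv) == len(self.icp_sd_or_par)):
            raise ValueError("time and both channels must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isnan(self.sensor_distance_L) and self.sensor_distance_L <= 0:
            raise ValueError("sensor_distance_L must be positive")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.ptp(dt) > 1e-6 * max(abs(dt[0]), 1e-30):
                raise ValueError("time grid must be uniform to within 1 ppm")

    @property
    def duration(self) -> float:
        return len(self.time) / self.sampling_rate


@dataclass
class GradientWindow:
    """One vetted 6-minute segment of the dICP waveform."""

    dicp: np.ndarray  # mmHg/m, zero-mean when accepted
    sampling_rate: float
    start_offset: float  # s from recording start
    accepted: bool
    raw_difference_range: float  # mmHg, max-min of the raw pressure difference
    state: str = "unknown"  # sleeping | awake | unknown
    patient_id: str = ""
    window_index: int = -1

    @property
    def duration(self) -> float:
        return len(self.dicp) / self.sampling_rate


def compute_dicp(rec: ICPRecording) -> np.ndarray:
    """Differential ICP, (ICP_SD|PAR − ICP_IV)/L, mmHg/m, on the same grid."""
    return (rec.icp_sd_or_par - rec.icp_iv) / rec.sensor_distance_L


def categorize_state(start_offset_s: float, start_clock: Optional[str]) -> str:
    """Sleep/awake label from the window's start time of day.

    Sleeping iff the start falls in [00:00, 06:00); a missing wall clock
    yields "unknown" (excluded from sleep analysis).
    """
    if start_clock is None:
        return "unknown"
    h, m, s = (int(x) for x in str(start_clock).split(":"))
    start = _dt.datetime(2000, 1, 1, h, m, s) + _dt.timedelta(seconds=float(start_offset_s))
    tod = start.time()
    return "sleeping" if SLEEP_START <= tod < SLEEP_END else "awake"


def extract_windows(
    rec: ICPRecording,
    window_s: float = WINDOW_DURATION_S,
    threshold_mmhg: float = ACCEPTANCE_THRESHOLD_MMHG,
) -> list[GradientWindow]:
    """Cut consecutive non-overlapping windows and vet each one.

    Acceptance is evaluated on the raw pressure difference in mmHg (before
    division by L and before the mean shift): the window passes iff
    (max − min) < ``threshold_mmhg`` strictly and contains no missing
    samples. Accepted windows carry the zero-mean dICP; rejected ones keep
    the unshifted dICP for inspection. A trailing partial segment is
    discarded; a recording shorter than one window yields an empty list.
    """
    n_win = int(round(window_s * rec.sampling_rate))
    diff_raw = rec.icp_sd_or_par - rec.icp_iv  # mmHg
    dicp_full = compute_dicp(rec)
    windows: list[GradientWindow] = []
    for k in range(len(rec.time) // n_win):
        sl = slice(k * n_win, (k + 1) * n_win)
        seg_raw = diff_raw[sl]
        seg_dicp = dicp_full[sl]
        start_offset = k * n_win / rec.sampling_rate
        has_nan = bool(np.isnan(seg_raw).any())
        rng = float(np.nanmax(seg_raw) - np.nanmin(seg_raw)) if not has_nan else float("nan")
        accepted = (not has_nan) and rng < threshold_mmhg
        dicp = seg_dicp - np.mean(seg_dicp) if accepted else seg_dicp.copy()
        windows.append(
            GradientWindow(
                dicp=dicp,
                sampling_rate=rec.sampling_rate,
                start_offset=start_offset,
                accepted=accepted,
                raw_difference_range=rng,
                state=categorize_state(start_offset, rec.start_clock),
                patient_id=rec.patient_id,
                window_index=k,
            )
        )
    return windows


def window_index_table(windows: list[GradientWindow]) -> pd.DataFrame:
    """Per-window bookkeeping table (one row per window, CSV-friendly)."""
    return pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "window_index": [w.window_index for w in windows],
            "start_offset_s": [w.start_offset for w in windows],
            "state": [w.state for w in windows],
            "accepted": [w.accepted for w in windows],
            "raw_range_mmHg": [w.raw_difference_range for w in windows],
        }
    )
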