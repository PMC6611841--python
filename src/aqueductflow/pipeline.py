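"""End-to-end orchestration: recordings → windows → spectra → flow → cohort.

Thin glue over the stage modules so the command line, the analysis
scripts and the tests all run the identical path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .cohort import summarize_patient, summarize_cohort, window_flow_table
from .recordings import ICPRecording, extract_windows, window_index_table
from .spectral import analyze_window

logger = logging.getLogger(__name__)

__all__ = ["PatientResult", "analyze_recording", "analyze_cohort"]


@dataclass
class PatientResult:
    patient_id: str
    window_index: pd.DataFrame  # all windows, accepted or not
    window_flow: pd.DataFrame  # accepted windows only
    patient_summary: pd.Series | None  # None when excluded


def analyze_recording(rec: ICPRecording, cfg: PipelineConfig | None = None) -> PatientResult:
    """Run one recording through windowing, spectral extraction and the
    analytical flow model."""
    cfg = cfg or PipelineConfig()
    windows = extract_windows(rec, cfg.window_s, cfg.acceptance_threshold_mmhg)
    idx = window_index_table(windows)
    accepted = [w for w in windows if w.accepted]
    logger.info(
        "patient %s: %d/%d windows accepted", rec.patient_id, len(accepted), len(windows)
    )
    summaries = [analyze_window(w, cfg.spectral) for w in accepted]
    flow = window_flow_table(summaries, cfg.geometry, cfg.fluid)
    summary = summarize_patient(flow) if not flow.empty else None
    return PatientResult(rec.patient_id, idx, flow, summary)


def analyze_cohort(
    recordings: list[ICPRecording], cfg: PipelineConfig | None = None
) -> tuple[list[PatientResult], pd.DataFrame, pd.Series | None]:
    """Analyze several patients and aggregate across them.

    Returns (per-patient results, patient-summary table of included
    patients, cohort row or None if no patient qualified). Patients whose
    recordings yield fewer than two accepted windows are excluded and
    logged.
    """
    cfg = cfg or PipelineConfig()
    results = [analyze_recording(rec, cfg) for rec in recordings]
    included = [r.patient_summary for r in results if r.patient_summary is not None]
    excluded = [r.patient_id for r in results if r.patient_summary is None]
    if excluded:
        logger.warning("excluded patients (insufficient accepted windows): %s", excluded)
    if not included:
        return results, pd.DataFrame(), None
    patient_table = pd.DataFrame(included)
    cohort_row = summarize_cohort(patient_table)
    return results, patient_table, cohort_row
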