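"""Cohort aggregation: per-patient and cross-patient summaries, the
sleep/awake comparison, and the reference-table replay.

Aggregation convention: quantities are averaged per window within each
patient first (ratios as per-window ratios, not ratios of means); cohort
statistics are the mean ± sample SD (n−1) across patient means, never
pooled windows. Patients with fewer than two accepted windows are
excluded, mirroring the clinical pipeline's exclusion rule.

The module also ships a reference table of published per-patient dICP
statistics (9 iNPH patients monitored overnight with paired intracranial
sensors: mean heart/respiratory rates and cardiac/respiratory gradient
amplitudes). Replaying this table through the analytical cylinder model
reproduces the headline result — cardiac-dominated pressure gradients,
respiration-dominated flow volumes — without access to the raw recordings.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .spectral import SpectrumSummary
from .womersley import AqueductGeometry, FluidProperties, summarize_window_flow

__all__ = [
    "MIN_WINDOWS_PER_PATIENT",
    "load_reference_cohort",
    "summarize_patient",
    "summarize_cohort",
    "sleep_vs_awake_test",
    "period_ratio",
    "replay_gradient_table",
    "window_flow_table",
]

logger = logging.getLogger(__name__)

MIN_WINDOWS_PER_PATIENT = 2

#: Quantities aggregated per patient (column names of the window table).
_WINDOW_QUANTITIES = [
    "heart_rate_bpm",
    "resp_rate_bpm",
    "cardiac_grad_mmHg_per_m",
    "resp_grad_mmHg_per_m",
    "grad_amplitude_ratio",
    "cardiac_pvf_mL_s",
    "resp_pvf_mL_s",
    "asv_uL",
    "arv_uL",
    "pvf_ratio",
    "volume_ratio",
]


def load_reference_cohort() -> pd.DataFrame:
    """Published per-patient dICP statistics (9 iNPH patients)."""
    with importlib.resources.files("aqueductflow.data").joinpath(
        "inph_cohort_gradients.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def window_flow_table(
    summaries: list[SpectrumSummary],
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> pd.DataFrame:
    """Per-window gradient + flow quantities from spectral summaries."""
    rows = []
    for s in summaries:
        flow = summarize_window_flow(s.a0_cardiac, s.f0_cardiac, s.a1_resp, s.f1_resp, geom, fluid)
        pid = s.window_ref.split(":")[0] if ":" in s.window_ref else s.window_ref
        rows.append(
            {
                "patient_id": pid,
                "window_ref": s.window_ref,
                "state": s.state,
                "heart_rate_bpm": s.f0_cardiac * 60.0,
                "resp_rate_bpm": s.f1_resp * 60.0,
                "cardiac_grad_mmHg_per_m": s.a0_cardiac,
                "resp_grad_mmHg_per_m": s.a1_resp,
                "grad_amplitude_ratio": s.a0_cardiac / s.a1_resp if s.a1_resp > 0 else math.nan,
                "cardiac_pvf_mL_s": flow.cardiac_pvf_mls,
                "resp_pvf_mL_s": flow.resp_pvf_mls,
                "asv_uL": flow.asv_ul,
                "arv_uL": flow.arv_ul,
                "pvf_ratio": flow.pvf_ratio,
                "volume_ratio": flow.volume_ratio,
            }
        )
    return pd.DataFrame(rows)


def summarize_patient(
    window_table: pd.DataFrame, min_windows: int = MIN_WINDOWS_PER_PATIENT
) -> pd.Series | None:
    """Mean ± sample SD over a patient's accepted windows.

    Returns None (patient excluded, logged) when fewer than ``min_windows``
    windows are available — by default 2, the clinical exclusion rule. SDs
    are reported only for n ≥ 2.
    """
    n = len(window_table)
    if n < 1:
        return None
    pid = window_table["patient_id"].iloc[0] if "patient_id" in window_table else ""
    if n < min_windows:
        logger.info("patient %s excluded: only %d accepted window(s)", pid, n)
        return None
    out: dict[str, float | str | int] = {"patient_id": pid, "n_windows": n}
    for col in _WINDOW_QUANTITIES:
        if col not in window_table:
            continue
        vals = window_table[col].astype(float)
        out[f"{col}_mean"] = float(vals.mean())
        out[f"{col}_sd"] = float(vals.std(ddof=1)) if n >= 2 else math.nan
    if "state" in window_table:
        for state in ("sleeping", "awake"):
            sub = window_table[window_table["state"] == state]
            for col in _WINDOW_QUANTITIES:
                if col in sub and len(sub) > 0:
                    out[f"{col}_{state}"] = float(sub[col].astype(float).mean())
    return pd.Series(out)


def summarize_cohort(patient_table: pd.DataFrame) -> pd.Series:
    """Mean ± sample SD across patient means (never pooled windows)."""
    out: dict[str, float | int] = {"n_patients": len(patient_table)}
    few = len(patient_table) < 2
    for col in patient_table.columns:
        if not col.endswith("_mean"):
            continue
        base = col[: -len("_mean")]
        vals = patient_table[col].astype(float)
        out[f"{base}_mean"] = float(vals.mean())
        out[f"{base}_sd"] = math.nan if few else float(vals.std(ddof=1))
    return pd.Series(out)


def sleep_vs_awake_test(
    patient_table: pd.DataFrame,
    quantities: tuple[str, ...] = (
        "cardiac_grad_mmHg_per_m",
        "resp_grad_mmHg_per_m",
        "heart_rate_bpm",
        "resp_rate_bpm",
    ),
) -> pd.DataFrame:
    """Two-sided paired t-test (sleeping vs awake patient sub-means).

    Patients missing either state are excluded pairwise. With fewer than
    two complete pairs, or zero variance of the differences, the test is
    reported as degenerate (NaN statistic, note in the row).
    """
    rows = []
    for q in quantities:
        s_col, a_col = f"{q}_sleeping", f"{q}_awake"
        if s_col not in patient_table or a_col not in patient_table:
            rows.append({"quantity": q, "n_pairs": 0, "t": math.nan, "p": math.nan,
                         "note": "missing state sub-means"})
            continue
        sub = patient_table[[s_col, a_col]].dropna()
        n = len(sub)
        if n < 2:
            rows.append({"quantity": q, "n_pairs": n, "t": math.nan, "p": math.nan,
                         "note": "fewer than 2 complete pairs"})
            continue
        d = sub[s_col].to_numpy() - sub[a_col].to_numpy()
        if np.allclose(d, d[0]):
            if np.allclose(d, 0.0):
                rows.append({"quantity": q, "n_pairs": n, "t": 0.0, "p": 1.0,
                             "note": "identical sub-means"})
            else:
                rows.append({"quantity": q, "n_pairs": n, "t": math.nan, "p": math.nan,
                             "note": "zero-variance differences (degenerate)"})
            continue
        t_stat, p_val = stats.ttest_rel(sub[s_col], sub[a_col])
        rows.append({"quantity": q, "n_pairs": n, "t": float(t_stat), "p": float(p_val),
                     "note": ""})
    return pd.DataFrame(rows)


def period_ratio(patient_table: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """Cardiac-to-respiratory period ratio, per patient and cohort.

    The cardiac period divided by the respiratory period equals the
    respiratory rate divided by the heart rate. Returns (cohort mean,
    cohort SD, per-patient series).
    """
    hr_col = "heart_rate_bpm_mean" if "heart_rate_bpm_mean" in patient_table else "heart_rate_bpm"
    rr_col = "resp_rate_bpm_mean" if "resp_rate_bpm_mean" in patient_table else "resp_rate_bpm"
    ratios = patient_table[rr_col].astype(float) / patient_table[hr_col].astype(float)
    sd = float(ratios.std(ddof=1)) if len(ratios) >= 2 else math.nan
    return float(ratios.mean()), sd, ratios


def replay_gradient_table(
    table: pd.DataFrame,
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Drive the analytical cylinder model from per-patient mean gradients.

    Each row must carry heart_rate_bpm, resp_rate_bpm,
    cardiac_grad_mmHg_per_m and resp_grad_mmHg_per_m. Returns the
    per-patient flow table and the cohort row (mean ± SD across patients).
    """
    rows = []
    for _, r in table.iterrows():
        f0 = units.per_minute_to_hz(float(r["heart_rate_bpm"]))
        f1 = units.per_minute_to_hz(float(r["resp_rate_bpm"]))
        flow = summarize_window_flow(
            float(r["cardiac_grad_mmHg_per_m"]), f0, float(r["resp_grad_mmHg_per_m"]), f1,
            geom, fluid,
        )
        rows.append(
            {
                "patient_id": r.get("patient_id", ""),
                "heart_rate_bpm": float(r["heart_rate_bpm"]),
                "resp_rate_bpm": float(r["resp_rate_bpm"]),
                "cardiac_grad_mmHg_per_m": float(r["cardiac_grad_mmHg_per_m"]),
                "resp_grad_mmHg_per_m": float(r["resp_grad_mmHg_per_m"]),
                "grad_amplitude_ratio": float(r["cardiac_grad_mmHg_per_m"])
                / float(r["resp_grad_mmHg_per_m"]),
                "cardiac_pvf_mL_s": flow.cardiac_pvf_mls,
                "resp_pvf_mL_s": flow.resp_pvf_mls,
                "asv_uL": flow.asv_ul,
                "arv_uL": flow.arv_ul,
                "pvf_ratio": flow.pvf_ratio,
                "volume_ratio": flow.volume_ratio,
                "period_ratio": f1 / f0,
            }
        )
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        return per_patient, pd.Series(dtype=float)
    numeric = per_patient.drop(columns=["patient_id"])
    cohort = pd.Series(
        {
            **{f"{c}_mean": float(numeric[c].mean()) for c in numeric.columns},
            **{
                f"{c}_sd": float(numeric[c].std(ddof=1)) if len(numeric) >= 2 else math.nan
                for c in numeric.columns
            },
            "n_patients": len(per_patient),
        }
    )
    return per_patient, cohort
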