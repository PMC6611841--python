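"""Unit conversions.

All internal computation is in SI (Pa, m, s, kg). Clinical units (mmHg,
mmHg/m, mL/s, μL) appear only at I/O boundaries, converted through the
single constant below so no stage drifts from another.
"""

MMHG_TO_PA: float = 133.322
"""Pascals per millimetre of mercury."""

SECONDS_PER_DAY: float = 86400.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def mmhg_per_m_to_pa_per_m(g: float) -> float:
    return g * MMHG_TO_PA


def pa_per_m_to_mmhg_per_m(g: float) -> float:
    return g / MMHG_TO_PA


def m3s_to_mls(q: float) -> float:
    """Volumetric flow rate, m³/s → mL/s."""
    return q * 1e6


def m3_to_ul(v: float) -> float:
    """Volume, m³ → μL."""
    return v * 1e9


def per_minute_to_hz(rate: float) -> float:
    return rate / 60.0
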