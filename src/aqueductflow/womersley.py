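"""Analytical pulsatile flow in a rigid cylindrical cerebral aqueduct.

The aqueduct is idealised as a rigid straight cylinder of radius R filled
with CSF (Newtonian, density ρ, viscosity μ). For an axial pressure
gradient that is a single sinusoid, the axisymmetric Navier–Stokes
equations reduce to a linear 1-D diffusion equation in the radius whose
periodic solution is the classical Womersley flow. The key dimensionless
group is the Womersley number

    α = R √(ωρ/μ),   ω = 2πf,

the ratio of oscillatory inertia to viscous forces. For a gradient
component a·sin(ωt + φ) the complex flow-rate amplitude is

    Q̂ = π R² (i a / ρω) [1 − (2/Λ) J₁(Λ)/J₀(Λ)],   Λ = α·i^{3/2},

with J₀, J₁ Bessel functions of the first kind, and the physical flow rate
is Q(t) = Im{Q̂ e^{i(ωt+φ)}}. The peak volumetric flow rate (PVF) is |Q̂|,
and because a sinusoidal flow of amplitude A at frequency f displaces a
volume A/(πf) per half-cycle, slow components move disproportionately
large volumes: at equal PVF, the volume ratio equals the inverse frequency
ratio. That momentum-accumulation effect is why respiration, despite a
much smaller pressure-gradient amplitude, dominates aqueductal flow
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import jv

from . import units

__all__ = [
    "AqueductGeometry",
    "FluidProperties",
    "HarmonicComponent",
    "HarmonicGradient",
    "HarmonicFlowSolution",
    "FlowSummary",
    "womersley_number",
    "womersley_solution",
    "flow_rate_series",
    "harmonic_volume",
    "velocity_profile",
    "poiseuille_static_gradient",
    "summarize_window_flow",
]

# i^{3/2} on the principal branch: e^{i 3π/4}
_I_3_2 = complex(math.cos(3 * math.pi / 4), math.sin(3 * math.pi / 4))


@dataclass(frozen=True)
class AqueductGeometry:
    """Rigid-cylinder aqueduct; default radius 2 mm (median iNPH aqueduct
    area ≈ 14 mm²)."""

    radius_R: float = 2e-3  # m

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise ValueError(f"radius_R must be positive, got {self.radius_R}")


@dataclass(frozen=True)
class FluidProperties:
    """CSF treated as water at body temperature."""

    density_rho: float = 1000.0  # kg/m^3
    viscosity_mu: float = 0.7e-3  # Pa s

    def __post_init__(self) -> None:
        if self.density_rho <= 0 or self.viscosity_mu <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class HarmonicComponent:
    """One sinusoidal pressure-gradient component a·sin(2πft + φ), SI units."""

    amplitude: float  # Pa/m
    frequency: float  # Hz
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")

    @classmethod
    def from_mmhg_per_m(
        cls, amplitude_mmhg_m: float, frequency: float, phase: float = 0.0
    ) -> "HarmonicComponent":
        return cls(units.mmhg_per_m_to_pa_per_m(amplitude_mmhg_m), frequency, phase)


@dataclass(frozen=True)
class HarmonicGradient:
    """Multi-component sinusoidal pressure gradient (superposition holds
    because the reduced momentum equation is linear)."""

    components: tuple[HarmonicComponent, ...] = ()

    @classmethod
    def from_components(cls, comps: Sequence[HarmonicComponent]) -> "HarmonicGradient":
        return cls(tuple(comps))


@dataclass(frozen=True)
class HarmonicFlowSolution:
    """Womersley solution for one gradient component."""

    omega: float  # rad/s
    womersley_alpha: float
    Lambda: complex
    pvf_amplitude_A: float  # m^3/s, = |Q̂|
    flow_phase: float  # rad, arg(Q̂) + forcing phase
    complex_amplitude: complex = field(repr=False, default=0j)  # Q̂ e^{iφ}


@dataclass(frozen=True)
class FlowSummary:
    """Per-window (or per-patient) flow quantities in reporting units."""

    cardiac_pvf_mls: float
    resp_pvf_mls: float
    asv_ul: float
    arv_ul: float
    pvf_ratio: float  # cardiac / respiratory
    volume_ratio: float  # ASV / ARV


def womersley_number(f: float, geom: AqueductGeometry, fluid: FluidProperties) -> float:
    """α = R √(2πf ρ/μ)."""
    omega = 2 * math.pi * f
    return geom.radius_R * math.sqrt(omega * fluid.density_rho / fluid.viscosity_mu)


def _bessel_bracket(Lambda: complex) -> complex:
    """[1 − (2/Λ) J₁(Λ)/J₀(Λ)], stable for |Λ| up to ~10².

    J₀ and J₁ grow like e^{|Im Λ|} at the same rate along the i^{3/2} ray,
    so the ratio stays O(1); scipy's complex jv handles the range needed
    (α ≤ 100 → |Λ| ≤ 100, well inside double-precision overflow limits).
    """
    return 1.0 - (2.0 / Lambda) * jv(1, Lambda) / jv(0, Lambda)


def womersley_solution(
    a: float,
    f: float,
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
    phase: float = 0.0,
) -> HarmonicFlowSolution:
    """Flow-rate amplitude and phase for a gradient component a·sin(2πft+φ).

    Parameters
    ----------
    a : pressure-gradient amplitude, Pa/m (must be ≥ 0).
    f : frequency, Hz (must be > 0; for the steady problem use
        :func:`poiseuille_static_gradient`).

    Returns
    -------
    HarmonicFlowSolution with the peak volumetric flow rate
    ``pvf_amplitude_A = |Q̂|`` in m³/s.
    """
    if f <= 0:
        raise ValueError(
            "womersley_solution requires f > 0; for a steady gradient use "
            "poiseuille_static_gradient"
        )
    if a < 0:
        raise ValueError("gradient amplitude must be non-negative")
    omega = 2 * math.pi * f
    alpha = womersley_number(f, geom, fluid)
    Lambda = alpha * _I_3_2
    q_hat = (
        math.pi
        * geom.radius_R**2
        * (1j * a / (fluid.density_rho * omega))
        * _bessel_bracket(Lambda)
    )
    q_hat_ph = q_hat * np.exp(1j * phase)
    return HarmonicFlowSolution(
        omega=omega,
        womersley_alpha=alpha,
        Lambda=Lambda,
        pvf_amplitude_A=abs(q_hat),
        flow_phase=float(np.angle(q_hat_ph)),
        complex_amplitude=q_hat_ph,
    )


def flow_rate_series(
    gradient: HarmonicGradient,
    geom: AqueductGeometry,
    fluid: FluidProperties,
    t: np.ndarray,
) -> np.ndarray:
    """Superposed flow rate Q(t) on a time grid, m³/s.

    Each component contributes Im{Q̂ e^{i(ωt+φ)}}; an empty component list
    yields a zero series.
    """
    t = np.asarray(t, dtype=float)
    q = np.zeros_like(t)
    for comp in gradient.components:
        sol = womersley_solution(comp.amplitude, comp.frequency, geom, fluid, comp.phase)
        q += np.imag(sol.complex_amplitude * np.exp(1j * sol.omega * t))
    return q


def harmonic_volume(sol: HarmonicFlowSolution) -> float:
    """Volume displaced per half-cycle, V = A/(πf), m³.

    Integral of A sin(2πft) over one half-period — the stroke volume for a
    cardiac component (ASV) and the respiratory volume (ARV) for a
    respiratory one.
    """
    f = sol.omega / (2 * math.pi)
    if f <= 0:
        raise ValueError("harmonic_volume requires a positive frequency")
    return sol.pvf_amplitude_A / (math.pi * f)


def velocity_profile(
    a: float,
    f: float,
    geom: AqueductGeometry,
    fluid: FluidProperties,
    r: np.ndarray | float,
    t: np.ndarray | float,
    phase: float = 0.0,
) -> np.ndarray:
    """Axial velocity v(r, t), m/s, for one gradient component.

    v(r,t) = Im{ (i a/ρω) [1 − J₀(Λ r/R)/J₀(Λ)] e^{i(ωt+φ)} }.
    Broadcasts over ``r`` and ``t``; enforces no-slip v(R, t) = 0.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0) or np.any(r > geom.radius_R):
        raise ValueError("radial positions must lie in [0, R]")
    if f <= 0:
        raise ValueError("velocity_profile requires f > 0")
    omega = 2 * math.pi * f
    alpha = womersley_number(f, geom, fluid)
    Lambda = alpha * _I_3_2
    v_hat = (1j * a / (fluid.density_rho * omega)) * (
        1.0 - jv(0, Lambda * r / geom.radius_R) / jv(0, Lambda)
    )
    return np.imag(
        v_hat * np.exp(1j * (omega * t + phase))
    )


def poiseuille_static_gradient(
    q_net: float,
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Steady pressure gradient driving a net flow, dp/dz = 8 μ Q/(π R⁴), Pa/m.

    Used to quantify the tiny static gradient implied by bulk CSF
    production (~500 mL/day) through the aqueduct.
    """
    if q_net < 0:
        raise ValueError("net flow must be non-negative")
    return 8.0 * fluid.viscosity_mu * q_net / (math.pi * geom.radius_R**4)


def summarize_window_flow(
    cardiac_amplitude_mmhg_m: float,
    cardiac_freq_hz: float,
    resp_amplitude_mmhg_m: float,
    resp_freq_hz: float,
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> FlowSummary:
    """Map one window's two-component gradient to PVFs, ASV, ARV and ratios.

    Amplitudes in mmHg/m (clinical convention); output in mL/s and μL.
    A zero respiratory amplitude yields NaN ratios (reported missing).
    """
    sol_c = womersley_solution(
        units.mmhg_per_m_to_pa_per_m(cardiac_amplitude_mmhg_m), cardiac_freq_hz, geom, fluid
    )
    sol_r = womersley_solution(
        units.mmhg_per_m_to_pa_per_m(resp_amplitude_mmhg_m), resp_freq_hz, geom, fluid
    )
    asv = harmonic_volume(sol_c)
    arv = harmonic_volume(sol_r)
    pvf_ratio = (
        sol_c.pvf_amplitude_A / sol_r.pvf_amplitude_A if sol_r.pvf_amplitude_A > 0 else math.nan
    )
    volume_ratio = asv / arv if arv > 0 else math.nan
    return FlowSummary(
        cardiac_pvf_mls=units.m3s_to_mls(sol_c.pvf_amplitude_A),
        resp_pvf_mls=units.m3s_to_mls(sol_r.pvf_amplitude_A),
        asv_ul=units.m3_to_ul(asv),
        arv_ul=units.m3_to_ul(arv),
        pvf_ratio=pvf_ratio,
        volume_ratio=volume_ratio,
    )
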