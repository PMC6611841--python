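"""Radial finite-difference solver for pulsatile pipe flow.

Independent numerical check of the analytical Womersley solution: the
axisymmetric momentum balance

    ρ ∂v/∂t − (μ/r) ∂v/∂r − μ ∂²v/∂r² = −dp/dz(t),   0 ≤ r ≤ R,

is integrated with a Crank–Nicolson scheme (second order in space and
time, unconditionally stable) on a uniform radial grid, with no-slip at
the wall and the symmetry condition ∂v/∂r = 0 at the axis. The 1/r
coordinate singularity at r = 0 is handled by the standard symmetry
expansion: near the axis (1/r)∂v/∂r → ∂²v/∂r², discretised with a ghost
point v(−Δr) = v(Δr).

Starting from rest, the solution carries a viscous transient that decays
on the timescale τ = R²/(ν j₀₁²) (j₀₁ ≈ 2.405, the first zero of J₀);
enough whole forcing periods are simulated for the transient to drop
below the analysis tolerance before the final period is examined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import jn_zeros

from .womersley import AqueductGeometry, FluidProperties, HarmonicGradient

__all__ = ["RadialGrid", "RadialFlowSolution", "solve_radial_flow", "periodic_amplitude"]

_J01_SQ = float(jn_zeros(0, 1)[0]) ** 2  # ≈ 5.783


@dataclass(frozen=True)
class RadialGrid:
    """Discretisation parameters.

    ``dt`` may be left None to derive it from the forcing (``steps_per_period``
    steps per period of the highest frequency). ``n_periods`` is the minimum
    number of whole lowest-frequency periods simulated; more are added
    automatically until the start-from-rest transient has decayed through
    ``settle_time_constants`` viscous time constants before the analysed
    final period.
    """

    n_points: int = 96  # radial intervals (n_points+1 nodes)
    dt: float | None = None
    n_periods: int = 6
    steps_per_period: int = 256
    settle_time_constants: float = 10.0

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be at least 16")
        if self.n_periods < 2:
            raise ValueError("need at least 2 periods (transient + analysis)")
        if self.steps_per_period < 100:
            raise ValueError("need at least 100 time steps per period")


@dataclass
class RadialFlowSolution:
    t: np.ndarray  # s
    r: np.ndarray  # m
    v: np.ndarray  # (nt, nr) m/s
    q: np.ndarray  # (nt,) m^3/s, radial quadrature of 2πr·v
    analysis_start: float  # s, start of the final (analysed) period


GradientLike = Union[HarmonicGradient, Callable[[np.ndarray], np.ndarray]]


def _forcing(gradient: GradientLike) -> tuple[Callable[[np.ndarray], np.ndarray], float, float, float]:
    """Return (dp/dz(t), f_min, f_max, amplitude scale)."""
    if callable(gradient):
        # steady or user-supplied forcing: caller controls duration via grid
        probe = float(np.max(np.abs(gradient(np.linspace(0.0, 1.0, 11)))))
        return gradient, 0.0, 0.0, max(probe, 1e-300)

    comps = gradient.components
    if not comps:
        raise ValueError("gradient has no components")
    freqs = [c.frequency for c in comps]
    if min(freqs) <= 0:
        raise ValueError("all component frequencies must be positive")

    def dpdz(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in comps:
            out += c.amplitude * np.sin(2 * math.pi * c.frequency * t + c.phase)
        return out

    scale = sum(c.amplitude for c in comps)
    return dpdz, min(freqs), max(freqs), max(scale, 1e-300)


def solve_radial_flow(
    gradient: GradientLike,
    geom: AqueductGeometry = AqueductGeometry(),
    fluid: FluidProperties = FluidProperties(),
    grid: RadialGrid = RadialGrid(),
    duration: float | None = None,
) -> RadialFlowSolution:
    """Time-step the radial momentum equation from rest.

    ``gradient`` is either a :class:`HarmonicGradient` (sinusoidal
    components; duration chosen automatically) or a callable t → dp/dz
    (e.g. a constant for the steady/Poiseuille check; ``duration`` and
    ``grid.dt`` must then be supplied).

    Raises RuntimeError if the solution grows beyond 10× the steady-state
    scale of the forcing (instability guard; Crank–Nicolson should never
    trigger it).
    """
    R = geom.radius_R
    rho, mu = fluid.density_rho, fluid.viscosity_mu
    nu = mu / rho
    dpdz, f_min, f_max, scale = _forcing(gradient)

    tau = R**2 / (nu * _J01_SQ)  # slowest viscous decay time
    if f_min > 0:
        T_low = 1.0 / f_min
        dt = grid.dt if grid.dt is not None else 1.0 / (f_max * grid.steps_per_period)
        if dt * f_max > 1.0 / 100:
            raise ValueError("dt must resolve the highest frequency with >= 100 steps/period")
        n_settle = math.ceil(grid.settle_time_constants * tau / T_low)
        n_per = max(grid.n_periods, n_settle + 1)
        t_end = n_per * T_low
        analysis_start = (n_per - 1) * T_low
    else:
        if duration is None or grid.dt is None:
            raise ValueError("callable forcing requires explicit duration and grid.dt")
        dt = grid.dt
        t_end = duration
        analysis_start = t_end

    n_r = grid.n_points
    dr = R / n_r
    r = np.arange(n_r + 1) * dr
    n_t = int(round(t_end / dt))
    t = np.arange(n_t + 1) * dt

    # interior operator L v = nu (v_rr + v_r / r); unknowns j = 0..n_r-1
    n_u = n_r
    lower = np.zeros(n_u)
    diag = np.zeros(n_u)
    upper = np.zeros(n_u)
    # axis (j = 0): L v = 2 nu v_rr with ghost v[-1] = v[1] -> 4 nu (v1 - v0)/dr^2
    diag[0] = -4.0 * nu / dr**2
    upper[0] = 4.0 * nu / dr**2
    for j in range(1, n_u):
        rj = r[j]
        lower[j] = nu / dr**2 - nu / (2 * rj * dr)
        diag[j] = -2.0 * nu / dr**2
        upper[j] = nu / dr**2 + nu / (2 * rj * dr)
    # j = n_r - 1 couples to the wall node v[n_r] = 0: upper entry drops out

    # Crank-Nicolson banded matrices: (I - dt/2 L) and (I + dt/2 L)
    ab_left = np.zeros((3, n_u))
    ab_left[0, 1:] = -0.5 * dt * upper[:-1]
    ab_left[1, :] = 1.0 - 0.5 * dt * diag
    ab_left[2, :-1] = -0.5 * dt * lower[1:]

    def apply_right(v_in: np.ndarray) -> np.ndarray:
        out = (1.0 + 0.5 * dt * diag) * v_in
        out[:-1] += 0.5 * dt * upper[:-1] * v_in[1:]
        out[1:] += 0.5 * dt * lower[1:] * v_in[:-1]
        return out

    # steady-state velocity scale for the instability guard
    v_scale = scale * R**2 / (4.0 * mu)
    guard = 10.0 * max(v_scale, 1e-300)

    v = np.zeros(n_u)
    v_hist = np.zeros((n_t + 1, n_r + 1))
    # momentum: rho v_t = mu(...) - dp/dz  =>  v_t = L v - dp/dz / rho
    t_mid = t[:-1] + 0.5 * dt
    force_mid = -np.asarray(dpdz(t_mid), dtype=float) / rho

    for k in range(n_t):
        rhs = apply_right(v) + dt * force_mid[k]
        v = solve_banded((1, 1), ab_left, rhs)
        if np.max(np.abs(v)) > guard:
            raise RuntimeError(
                f"radial solver unstable at t={t[k+1]:.3g}s: |v| exceeded 10x forcing scale"
            )
        v_hist[k + 1, :n_u] = v

    q = np.trapezoid(2 * math.pi * r * v_hist, r, axis=1)
    return RadialFlowSolution(t=t, r=r, v=v_hist, q=q, analysis_start=analysis_start)


def periodic_amplitude(t: np.ndarray, q: np.ndarray, f: float, t_start: float | None = None) -> float:
    """Amplitude of the f-component of a periodic series by Fourier projection.

    Projects q(t) onto e^{-i 2πf t} over [t_start, end of series]
    (default: the final period of f). The window should span a whole
    number of periods of f — and of any other component present — for the
    projection to be leakage-free; the caller controls this via t_start.
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    T = 1.0 / f
    if t_start is None:
        t_start = t[-1] - T
    mask = t >= t_start - 1e-12
    ts, qs = t[mask], q[mask]
    if ts.size < 8:
        raise ValueError("analysis interval too short for projection")
    span = ts[-1] - ts[0]
    proj = np.trapezoid(qs * np.exp(-2j * math.pi * f * ts), ts) * (2.0 / span)
    return float(abs(proj))
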