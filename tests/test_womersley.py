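"""Analytical Womersley flow: amplitudes, volumes, velocities, limits."""

import numpy as np
import pytest

from aqueductflow import (
    AqueductGeometry,
    FluidProperties,
    HarmonicComponent,
    HarmonicGradient,
    flow_rate_series,
    harmonic_volume,
    poiseuille_static_gradient,
    summarize_window_flow,
    units,
    velocity_profile,
    womersley_number,
    womersley_solution,
)

MMHG_M = units.MMHG_TO_PA  # Pa/m per mmHg/m


class TestAmplitude:
    def test_zero_amplitude_gives_zero_flow(self, geom, fluid):
        sol = womersley_solution(0.0, 1.0, geom, fluid)
        assert sol.pvf_amplitude_A == 0.0

    def test_patient2_cardiac_pvf(self, geom, fluid):
        # published patient-2 averages: 1.52 mmHg/m at 51 beats/min -> 0.38 mL/s
        sol = womersley_solution(1.52 * MMHG_M, 51 / 60, geom, fluid)
        assert units.m3s_to_mls(sol.pvf_amplitude_A) == pytest.approx(0.38, rel=0.10)

    def test_low_frequency_limit_is_poiseuille(self, geom, fluid):
        a = 1.0 * MMHG_M
        sol = womersley_solution(a, 1e-4, geom, fluid)
        poiseuille = np.pi * geom.radius_R**4 * a / (8 * fluid.viscosity_mu)
        assert sol.pvf_amplitude_A == pytest.approx(poiseuille, rel=1e-4)

    def test_high_womersley_limit_is_inertial(self, geom, fluid):
        # A -> pi R^2 a / (rho omega) as alpha -> infinity
        a = 1.0 * MMHG_M
        f = 200.0  # alpha ~ 85; the bracket correction decays like 1.4/alpha
        sol = womersley_solution(a, f, geom, fluid)
        assert sol.womersley_alpha > 50
        inertial = np.pi * geom.radius_R**2 * a / (fluid.density_rho * sol.omega)
        assert sol.pvf_amplitude_A == pytest.approx(inertial, rel=0.02)

    def test_linearity_in_amplitude(self, geom, fluid):
        base = womersley_solution(100.0, 1.0, geom, fluid).pvf_amplitude_A
        for k in (0.0, 0.5, 3.0, 17.0):
            assert womersley_solution(k * 100.0, 1.0, geom, fluid).pvf_amplitude_A == pytest.approx(
                k * base, rel=1e-12, abs=1e-300
            )

    def test_amplitude_decreases_with_frequency(self, geom, fluid):
        freqs = np.linspace(0.1, 5.0, 40)
        amps = [womersley_solution(100.0, f, geom, fluid).pvf_amplitude_A for f in freqs]
        assert np.all(np.diff(amps) < 0)

    def test_zero_frequency_directed_to_poiseuille(self, geom, fluid):
        with pytest.raises(ValueError, match="[Pp]oiseuille"):
            womersley_solution(100.0, 0.0, geom, fluid)


class TestFlowSeries:
    def test_single_component_is_sinusoid_of_amplitude_A(self, geom, fluid):
        a, f = 1.46 * MMHG_M, 1.0
        sol = womersley_solution(a, f, geom, fluid)
        t = np.linspace(0, 10, 20001)
        q = flow_rate_series(HarmonicGradient((HarmonicComponent(a, f),)), geom, fluid, t)
        assert np.max(np.abs(q)) == pytest.approx(sol.pvf_amplitude_A, rel=1e-6)

    def test_two_components_superpose(self, geom, fluid):
        c1 = HarmonicComponent(1.46 * MMHG_M, 1.0)
        c2 = HarmonicComponent(0.52 * MMHG_M, 0.25)
        t = np.linspace(0, 4.0, 4001)  # whole periods of both
        q_sum = flow_rate_series(HarmonicGradient((c1, c2)), geom, fluid, t)
        q1 = flow_rate_series(HarmonicGradient((c1,)), geom, fluid, t)
        q2 = flow_rate_series(HarmonicGradient((c2,)), geom, fluid, t)
        assert np.allclose(q_sum, q1 + q2, atol=1e-15)
        # Fourier projection recovers each component's amplitude
        for comp, q_ref in ((c1, q1), (c2, q2)):
            sol = womersley_solution(comp.amplitude, comp.frequency, geom, fluid)
            proj = np.abs(
                np.trapezoid(q_sum * np.exp(-2j * np.pi * comp.frequency * t), t) * 2 / 4.0
            )
            assert proj == pytest.approx(sol.pvf_amplitude_A, rel=1e-3)

    def test_empty_gradient_gives_zero_series(self, geom, fluid):
        t = np.linspace(0, 1, 100)
        assert np.all(flow_rate_series(HarmonicGradient(()), geom, fluid, t) == 0.0)


class TestVolumes:
    def test_volume_formula_matches_quadrature(self, geom, fluid):
        sol = womersley_solution(1.52 * MMHG_M, 0.85, geom, fluid)
        v = harmonic_volume(sol)
        # trapezoidal integral of A sin(2 pi f t) over a half period
        t = np.linspace(0, 0.5 / 0.85, 10001)
        v_num = np.trapezoid(sol.pvf_amplitude_A * np.sin(2 * np.pi * 0.85 * t), t)
        assert v == pytest.approx(v_num, rel=1e-6)

    def test_patient2_stroke_volume(self, geom, fluid):
        # published: ASV 144.4 uL for patient 2 (window-level averaging)
        sol = womersley_solution(1.52 * MMHG_M, 51 / 60, geom, fluid)
        assert units.m3_to_ul(harmonic_volume(sol)) == pytest.approx(144.4, rel=0.05)

    def test_zero_amplitude_gives_zero_volume(self, geom, fluid):
        sol = womersley_solution(0.0, 1.0, geom, fluid)
        assert harmonic_volume(sol) == 0.0

    def test_momentum_mechanism_volume_ratio_is_frequency_ratio(self, geom, fluid):
        """Equal flow amplitudes at frequency ratio 1:4 displace volumes 4:1."""
        f_fast, f_slow = 1.0, 0.25
        sol_fast = womersley_solution(100.0, f_fast, geom, fluid)
        # rescale the slow component's gradient so its flow amplitude matches
        a_slow = 100.0 * sol_fast.pvf_amplitude_A / womersley_solution(
            100.0, f_slow, geom, fluid
        ).pvf_amplitude_A
        sol_slow = womersley_solution(a_slow, f_slow, geom, fluid)
        assert sol_slow.pvf_amplitude_A == pytest.approx(sol_fast.pvf_amplitude_A, rel=1e-12)
        ratio = harmonic_volume(sol_slow) / harmonic_volume(sol_fast)
        assert ratio == pytest.approx(f_fast / f_slow, rel=1e-12)


class TestVelocity:
    def test_no_slip_at_wall(self, geom, fluid):
        v = velocity_profile(100.0, 1.0, geom, fluid, geom.radius_R, np.linspace(0, 2, 50))
        assert np.allclose(v, 0.0, atol=1e-18)

    def test_outside_radius_rejected(self, geom, fluid):
        with pytest.raises(ValueError):
            velocity_profile(100.0, 1.0, geom, fluid, 1.1 * geom.radius_R, 0.0)

    def test_profile_integrates_to_flow_rate(self, geom, fluid):
        a, f, t0 = 1.46 * MMHG_M, 62 / 60, 0.3
        r = np.linspace(0, geom.radius_R, 4001)
        v = velocity_profile(a, f, geom, fluid, r, t0)
        q_int = np.trapezoid(2 * np.pi * r * v, r)
        sol = womersley_solution(a, f, geom, fluid)
        q_exact = np.imag(sol.complex_amplitude * np.exp(1j * sol.omega * t0))
        assert q_int == pytest.approx(q_exact, rel=1e-3, abs=1e-12)

    def test_cohort_average_velocity_scale(self, geom, fluid):
        """Cohort-mean gradients drive peak velocities of a few cm/s with
        cross-sectional mean peaks around 3 cm/s — the reported scale."""
        r = np.linspace(0, geom.radius_R, 200)[None, :]
        t = np.linspace(0, 8, 1600)[:, None]
        v_card = velocity_profile(1.46 * MMHG_M, 62 / 60, geom, fluid, r, t)
        v_resp = velocity_profile(0.52 * MMHG_M, 15 / 60, geom, fluid, r, t)
        assert 0.02 < np.max(np.abs(v_card)) < 0.06
        assert 0.02 < np.max(np.abs(v_resp)) < 0.06
        area = np.pi * geom.radius_R**2
        for a, f in ((1.46 * MMHG_M, 62 / 60), (0.52 * MMHG_M, 15 / 60)):
            mean_peak = womersley_solution(a, f, geom, fluid).pvf_amplitude_A / area
            assert 0.015 < mean_peak < 0.035


class TestPoiseuille:
    def test_third_circulation_gradient(self, geom):
        q = 500e-6 / units.SECONDS_PER_DAY  # 500 mL/day in m^3/s
        for mu in (0.65e-3, 0.70e-3):
            g = poiseuille_static_gradient(q, geom, FluidProperties(viscosity_mu=mu))
            assert units.pa_per_m_to_mmhg_per_m(g) == pytest.approx(0.0045, rel=0.10)

    def test_zero_flow_zero_gradient(self, geom, fluid):
        assert poiseuille_static_gradient(0.0, geom, fluid) == 0.0

    def test_inverse_fourth_power_radius_scaling(self, fluid):
        q = 1e-8
        g1 = poiseuille_static_gradient(q, AqueductGeometry(2e-3), fluid)
        g2 = poiseuille_static_gradient(q, AqueductGeometry(1e-3), fluid)
        assert g2 == pytest.approx(16 * g1, rel=1e-12)


class TestWindowSummary:
    def test_patient2_pvf_ratio(self, geom, fluid):
        s = summarize_window_flow(1.52, 51 / 60, 0.46, 15 / 60, geom, fluid)
        assert s.pvf_ratio == pytest.approx(1.18, rel=0.10)

    def test_equal_components_give_unit_ratio(self, geom, fluid):
        s = summarize_window_flow(1.0, 1.0, 1.0, 1.0, geom, fluid)
        assert s.pvf_ratio == pytest.approx(1.0, rel=1e-12)
        assert s.volume_ratio == pytest.approx(1.0, rel=1e-12)

    def test_patient1_volume_ratio(self, geom, fluid):
        s = summarize_window_flow(1.59, 78 / 60, 0.72, 17 / 60, geom, fluid)
        assert s.volume_ratio == pytest.approx(0.13, rel=0.15)

    def test_missing_respiratory_component_gives_nan_ratios(self, geom, fluid):
        s = summarize_window_flow(1.5, 1.0, 0.0, 0.25, geom, fluid)
        assert np.isnan(s.pvf_ratio)
        assert np.isnan(s.volume_ratio)
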