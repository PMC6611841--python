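#!/usr/bin/env python
"""Cross-check the analytical flow amplitudes against the radial solver.

For Womersley numbers spanning the physiological range (respiratory ~2.7
to cardiac ~6, plus margins) the Crank-Nicolson finite-difference solution
of the radial momentum equation is compared with the closed-form
Bessel-function amplitude. Writes results/oracle_check.csv.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from aqueductflow import (
    AqueductGeometry,
    FluidProperties,
    HarmonicComponent,
    HarmonicGradient,
    RadialGrid,
    periodic_amplitude,
    solve_radial_flow,
    units,
    womersley_solution,
)

OUT = Path("results")


def main() -> None:
    geom, fluid = AqueductGeometry(), FluidProperties()
    nu = fluid.viscosity_mu / fluid.density_rho
    a = 1.5 * units.MMHG_TO_PA
    rows = []
    for alpha in (1.0, 3.0, 5.5, 10.0):
        f = alpha**2 * nu / (geom.radius_R**2 * 2 * math.pi)
        analytical = womersley_solution(a, f, geom, fluid).pvf_amplitude_A
        num = solve_radial_flow(
            HarmonicGradient((HarmonicComponent(a, f),)), geom, fluid, RadialGrid()
        )
        numeric = periodic_amplitude(num.t, num.q, f)
        rows.append(
            {
                "womersley_alpha": alpha,
                "frequency_Hz": f,
                "analytical_mL_s": units.m3s_to_mls(analytical),
                "finite_difference_mL_s": units.m3s_to_mls(numeric),
                "relative_difference": abs(numeric - analytical) / analytical,
            }
        )
        print(f"alpha {alpha:5.2f} (f = {f:.4f} Hz): analytical "
              f"{units.m3s_to_mls(analytical):.4f} mL/s, FD "
              f"{units.m3s_to_mls(numeric):.4f} mL/s, "
              f"rel diff {rows[-1]['relative_difference']:.2e}")

    # steady limit: constant forcing relaxes to the Poiseuille profile
    a_st = 200.0
    sol = solve_radial_flow(
        lambda t: np.full(np.shape(t), -a_st), geom, fluid,
        RadialGrid(n_points=96, dt=0.05), duration=30.0,
    )
    v_exact = a_st * (geom.radius_R**2 - sol.r**2) / (4 * fluid.viscosity_mu)
    err = float(np.max(np.abs(sol.v[-1] - v_exact)) / np.max(v_exact))
    print(f"steady forcing vs Poiseuille profile: max relative error {err:.2e}")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "oracle_check.csv", index=False)


if __name__ == "__main__":
    main()
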