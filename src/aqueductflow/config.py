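"""Pipeline configuration.

Every physical and methodological constant of the pipeline lives here —
the 2 mmHg window-acceptance threshold, the 360 s window, the spectral
bands and 15 Hz cutoff, the calibration factor C, the aqueduct radius and
fluid properties, the mmHg↔Pa conversion and the sleep interval — so no
stage hard-codes them. Configurations are round-trippable through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recordings import ACCEPTANCE_THRESHOLD_MMHG, WINDOW_DURATION_S
from .spectral import SpectralConfig
from .womersley import AqueductGeometry, FluidProperties

__all__ = ["PipelineConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    geometry: AqueductGeometry = field(default_factory=AqueductGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    window_s: float = WINDOW_DURATION_S
    acceptance_threshold_mmhg: float = ACCEPTANCE_THRESHOLD_MMHG
    decomposition_interpolant: str = "spline"
    decomposition_interval_s: float = 10.0
    output_dir: str = "results"
    seed: int = 0

    def warn_on_nonstandard(self) -> None:
        """Log a warning for each field departing from the reference setup."""
        ref = PipelineConfig()
        for name, refval, val in [
            ("window_s", ref.window_s, self.window_s),
            ("acceptance_threshold_mmhg", ref.acceptance_threshold_mmhg,
             self.acceptance_threshold_mmhg),
            ("lowpass_cutoff", ref.spectral.lowpass_cutoff, self.spectral.lowpass_cutoff),
            ("cardiac_band", ref.spectral.cardiac_band, self.spectral.cardiac_band),
            ("resp_band", ref.spectral.resp_band, self.spectral.resp_band),
            ("radius_R", ref.geometry.radius_R, self.geometry.radius_R),
            ("density_rho", ref.fluid.density_rho, self.fluid.density_rho),
            ("viscosity_mu", ref.fluid.viscosity_mu, self.fluid.viscosity_mu),
        ]:
            if val != refval:
                logger.warning("config %s = %r departs from reference value %r", name, val, refval)


def _to_dict(cfg: PipelineConfig) -> dict:
    return {
        "spectral": dataclasses.asdict(cfg.spectral),
        "geometry": dataclasses.asdict(cfg.geometry),
        "fluid": dataclasses.asdict(cfg.fluid),
        "window_s": cfg.window_s,
        "acceptance_threshold_mmhg": cfg.acceptance_threshold_mmhg,
        "decomposition_interpolant": cfg.decomposition_interpolant,
        "decomposition_interval_s": cfg.decomposition_interval_s,
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
    }


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing file or None yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    spectral = data.get("spectral", {})
    if "cardiac_band" in spectral:
        spectral["cardiac_band"] = tuple(spectral["cardiac_band"])
    if "resp_band" in spectral:
        spectral["resp_band"] = tuple(spectral["resp_band"])
    cfg = PipelineConfig(
        spectral=SpectralConfig(**spectral),
        geometry=AqueductGeometry(**data.get("geometry", {})),
        fluid=FluidProperties(**data.get("fluid", {})),
        window_s=data.get("window_s", WINDOW_DURATION_S),
        acceptance_threshold_mmhg=data.get(
            "acceptance_threshold_mmhg", ACCEPTANCE_THRESHOLD_MMHG
        ),
        decomposition_interpolant=data.get("decomposition_interpolant", "spline"),
        decomposition_interval_s=data.get("decomposition_interval_s", 10.0),
        output_dir=data.get("output_dir", "results"),
        seed=int(data.get("seed", 0)),
    )
    cfg.warn_on_nonstandard()
    return cfg
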