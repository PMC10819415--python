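"""Validated run configuration (JSON/YAML-friendly, unknown keys rejected).

The schema mirrors the library's domain objects: a beam block, a medium
block, threshold settings, render settings and the simulation grids.  All
lengths are µm, powers are relative (or mW when absolute), pixel data are
detector counts.  Defaults marked "measured" reproduce the characterised
instrument (1040 nm beam focused to a 0.55 µm waist); the rest are package
defaults.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .optics import BeamParameters
from .sbr import MediumProperties
from .stacks import ThresholdConfig
from .synth import RenderConfig

__all__ = [
    "BeamConfig",
    "MediumConfig",
    "ThresholdSettings",
    "RenderSettings",
    "SimulationGrid",
    "RunConfig",
    "load_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_StrictModel):
    """Excitation beam (measured defaults: 1040 nm, w0 = 0.55 µm)."""

    wavelength_um: float = Field(1.040, gt=0)
    waist_um: float = Field(0.55, gt=0)
    refractive_index: float = Field(1.33, ge=1)

    def to_beam(self) -> BeamParameters:
        return BeamParameters(
            wavelength_um=self.wavelength_um,
            waist_um=self.waist_um,
            refractive_index=self.refractive_index,
        )


class MediumConfig(_StrictModel):
    """Sample optics: scattering length, emission absorption, fill fraction."""

    scattering_length_um: float = Field(120.0, gt=0)
    absorption_length_um: float = Field(500.0, gt=0)
    fill_fraction: float = Field(0.10, gt=0, le=1)

    @field_validator("scattering_length_um", "absorption_length_um", mode="before")
    @classmethod
    def _allow_inf(cls, v):
        if isinstance(v, str) and v.lower() in ("inf", "infinity"):
            return math.inf
        return v

    def to_medium(self) -> MediumProperties:
        return MediumProperties(
            scattering_length_um=self.scattering_length_um,
            absorption_length_um=self.absorption_length_um,
            fill_fraction=self.fill_fraction,
        )


class ThresholdSettings(_StrictModel):
    """Histogram signal threshold, applied identically to every channel."""

    strategy: str = "brighter_fraction"
    count_threshold: int = Field(50, ge=1)
    brighter_fraction: float = Field(0.002, gt=0, lt=1)

    def to_threshold(self) -> ThresholdConfig:
        return ThresholdConfig(
            strategy=self.strategy,  # type: ignore[arg-type]
            count_threshold=self.count_threshold,
            brighter_fraction=self.brighter_fraction,
        )


class RenderSettings(_StrictModel):
    """Detector and rendering parameters for the synthetic stack generator."""

    z_step_um: float = Field(4.0, gt=0)
    detector_offset: int = Field(100, ge=0)
    photon_scale: float = Field(80.0, gt=0)
    read_noise_sd: float = Field(2.0, ge=0)
    texture_amplitude: float = Field(0.2, ge=0)
    texture_correlation_um: float = Field(10.0, gt=0)
    seed: int = 0

    def to_render(self, beam: BeamParameters, medium: MediumProperties) -> RenderConfig:
        return RenderConfig(
            beam=beam,
            medium=medium,
            z_step_um=self.z_step_um,
            detector_offset=self.detector_offset,
            photon_scale=self.photon_scale,
            read_noise_sd=self.read_noise_sd,
            texture_amplitude=self.texture_amplitude,
            texture_correlation_um=self.texture_correlation_um,
            seed=self.seed,
        )


class SimulationGrid(_StrictModel):
    """Depth / scattering-length grids for SBR sweeps and maps."""

    depth_min_um: float = Field(10.0, gt=0)
    depth_max_um: float = Field(1000.0, gt=0)
    n_depths: int = Field(100, ge=2)
    le_min_um: float = Field(40.0, gt=0)
    le_max_um: float = Field(300.0, gt=0)
    n_le: int = Field(30, ge=2)


class RunConfig(_StrictModel):
    """Top-level configuration tying all stages together."""

    beam: BeamConfig = Field(default_factory=BeamConfig)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    thresholds: ThresholdSettings = Field(default_factory=ThresholdSettings)
    render: RenderSettings = Field(default_factory=RenderSettings)
    simulation: SimulationGrid = Field(default_factory=SimulationGrid)

    def hash_params(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML (by extension); unknown keys error."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml  # deferred: YAML input is optional

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data or {})
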