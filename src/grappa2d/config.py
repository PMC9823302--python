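"""Experiment configuration: validated schema and shipped profiles."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["SimulationConfig", "SamplingConfig", "ExperimentConfig",
           "PROFILES", "load_config"]


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid: int = Field(64, ge=8)
    fov_mm: float = Field(192.0, gt=0)
    n_channels: int = Field(8, ge=4)
    n_clusters: int = Field(4, ge=1)
    loop_diameter_m: float = Field(0.072, gt=0)
    loop_gap_m: float = Field(0.001, gt=0)
    voi_side_m: float = Field(0.28, gt=0)
    n_segments: int = Field(128, ge=8)
    snr_db: Optional[float] = None  # None -> noiseless


class SamplingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    R_y: int = Field(2, ge=1)
    R_z: int = Field(2, ge=1)
    acs_y: int = Field(16, ge=0)
    acs_z: int = Field(16, ge=0)


class ExperimentConfig(BaseModel):
    """Full experiment description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = SimulationConfig()
    sampling: SamplingConfig = SamplingConfig()
    algorithms: list[str] = ["LK", "EX", "SK", "BK"]
    n_x: list[int] = [1]
    type_index: int = Field(4, ge=1, le=4)
    include_acs: bool = False
    seed: int = 0

    @classmethod
    def schema_json(cls) -> dict:
        return cls.model_json_schema()


#: shipped profiles: desk-scale for minutes-long experiments, full-scale
#: matching the reference simulation protocol (192^3 grid, 12 channels).
PROFILES: dict[str, ExperimentConfig] = {
    "desk": ExperimentConfig(),
    "full": ExperimentConfig(
        simulation=SimulationConfig(grid=192, n_channels=12, snr_db=30.0),
        sampling=SamplingConfig(R_y=2, R_z=2, acs_y=24, acs_z=24),
    ),
}


def load_config(path=None, profile: str = "desk") -> ExperimentConfig:
    """Load a YAML config file, or one of the shipped profiles."""
    if path is None:
        return PROFILES[profile].model_copy(deep=True)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)
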