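"""Typed, validated run configuration (YAML/JSON)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import InvalidParameterError


class SimulationConfig(BaseModel):
    """Synthetic-cohort settings (subset of CohortSpec, YAML-friendly)."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = 60
    n_rois: int = 20
    n_voxels: int = 1500
    subject_sd: float = 0.05
    n_planted_edges: int = 10
    target_r2: Optional[float] = 0.7
    noise_sd: float = 1.0
    laser_range: tuple[float, float] = (1.75, 4.25)
    cold_mean_sd: tuple[float, float] = (9.59, 0.38)


class RunConfig(BaseModel):
    """One prediction run: inputs, feature set, threshold, selection settings."""

    model_config = ConfigDict(extra="forbid")

    samples_path: Optional[str] = None  # long TSV or HDF5 of ROI samples
    phenotypes_path: Optional[str] = None  # CSV
    parcellation_path: Optional[str] = None  # CSV; default packaged table
    simulation: Optional[SimulationConfig] = None
    threshold: Literal["laser", "cold", "score"] = "laser"
    feature_set: Literal["mc", "gmv", "gmv_mc"] = "mc"
    mode: Literal["group_level", "nested"] = "nested"
    schedule: Optional[tuple[int, ...]] = None
    error_metric: Literal["mae", "mrae", "one_minus_r"] = "mae"
    inner_cv: int = 5
    max_components: int = 10
    standardize: bool = False
    seed: int = 0
    out_dir: str = "mcpain_out"

    @field_validator("schedule")
    @classmethod
    def _check_schedule(cls, v):
        if v is None:
            return v
        if any(b >= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly decreasing")
        if v[-1] != 1:
            raise ValueError("schedule must end at interval 1")
        return v

    @model_validator(mode="after")
    def _check_inputs(self):
        has_files = self.samples_path is not None and self.phenotypes_path is not None
        if not has_files and self.simulation is None:
            raise ValueError(
                "config needs either samples_path+phenotypes_path or a "
                "simulation block"
            )
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config; unknown keys are rejected."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"config {path} is not a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        raise InvalidParameterError(str(exc)) from exc
    for p in (cfg.samples_path, cfg.phenotypes_path, cfg.parcellation_path):
        if p is not None and not Path(p).exists():
            raise InvalidParameterError(f"referenced path does not exist: {p}")
    return cfg
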