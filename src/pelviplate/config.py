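"""Pipeline configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import DEFAULT_SEED

__all__ = ["PopulationConfig", "TrajectoryConfig", "PipelineConfig", "load_config"]


class PopulationConfig(BaseModel):
    """Parameters forwarded to the population generator."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(834, ge=2)
    anchor: Literal["total", "lpr"] = "total"
    total_mean: float = 214.46
    total_sd: float = Field(10.15, gt=0)
    lpr_mean: float = 60.96
    lpr_sd: float = Field(5.39, gt=0)
    x_mean: float = 69.11 / 60.96
    x_sd: float = Field(0.08, gt=0)
    slope: float = 0.731
    intercept: float = 0.559
    residual_sd: Optional[float] = Field(None, ge=0)
    target_r: float = Field(0.622, gt=0, lt=1)
    group_effects: bool = True


class TrajectoryConfig(BaseModel):
    """Parameters of the synthetic landmark fixtures."""

    model_config = ConfigDict(extra="forbid")

    count: int = Field(22, ge=0)
    noise_sd: float = Field(0.0, ge=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = DEFAULT_SEED
    tolerance_mm: float = Field(10.0, ge=0)
    rounding: Literal["half_up"] = "half_up"
    t_test_variant: Literal["pooled", "welch"] = "pooled"
    mode: Literal["design", "clinical"] = "design"
    population: PopulationConfig = PopulationConfig()
    trajectories: TrajectoryConfig = TrajectoryConfig()
    out_dir: str = "out"

    def digest(self) -> str:
        """Short stable hash of the configuration, for log lines."""
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML or JSON config; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
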