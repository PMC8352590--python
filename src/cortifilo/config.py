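"""Validated pipeline configuration (TOML or YAML).

Every key is type- and range-checked before any computation; unknown keys
are rejected, and all violations are reported at once (pydantic collects
them).  Defaults carry the method's constants: 0.8 µm cortical band,
360 angular bins, ROUT Q = 0.001, tip-search geometry, 5 spline knots.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .filopodia import TipSearchConfig
from .groupstats import RoutConfig
from .segment import SegmentationConfig

__all__ = ["PipelineConfig", "SimulationSpec", "ConditionSpec", "validate_config", "config_hash"]


class ConditionSpec(BaseModel):
    """One simulated condition: a name plus scene-parameter overrides."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_cells: int = 30
    n_experiments: int = 3
    params: dict = Field(default_factory=dict)  # SceneParams overrides

    @field_validator("n_cells", "n_experiments")
    @classmethod
    def _pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v


class SimulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conditions: list[ConditionSpec]


class CorticalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    band_width_um: float = 0.8
    n_bins: int = 360
    normalized_sd: bool = False

    @field_validator("band_width_um")
    @classmethod
    def _band(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("band_width_um must be positive")
        return v

    @field_validator("n_bins")
    @classmethod
    def _bins(cls, v: int) -> int:
        if v < 8:
            raise ValueError("n_bins must be >= 8")
        return v


class SplineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_knots: int = 5

    @field_validator("n_knots")
    @classmethod
    def _k(cls, v: int) -> int:
        if v < 3:
            raise ValueError("n_knots must be >= 3")
        return v


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rout: RoutConfig = Field(default_factory=RoutConfig)
    posthoc: str = "tukey"
    control: str | None = None
    star_cutpoints: tuple[float, float, float, float] = (0.05, 0.01, 0.001, 0.0001)


class IOConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pixel_size_um: float | None = None  # fallback when files carry none
    strict: bool = True
    inputs: list[str] = Field(default_factory=list)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "cortifilo_run"
    simulate: SimulationSpec | None = None
    io: IOConfig = Field(default_factory=IOConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    cortical: CorticalConfig = Field(default_factory=CorticalConfig)
    tips: TipSearchConfig = Field(default_factory=TipSearchConfig)
    spline: SplineConfig = Field(default_factory=SplineConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and validate a TOML/YAML config file, path or dict.

    Raises ``ValueError`` listing every violation at once.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            raw = tomllib.loads(text)
        else:
            raw = yaml.safe_load(text) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid configuration: {msgs}") from err


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
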