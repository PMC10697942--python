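"""Validated pipeline configuration (YAML file with CLI-flag overrides).

Defaults mirror the shipped method settings: 10° rotation step, edge-cost
coefficients c=0.01, d=1, r=0.01, PCK threshold at 20% of the torso
diameter, graph selector.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from .metrics import MetricConfig
from .trellis import CostParams


class CostConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c: float = 0.01
    d: float = 1.0
    r: float = 0.01
    confidence_floor: float = 1e-6

    def to_params(self) -> CostParams:
        return CostParams(c=self.c, d=self.d, r=self.r,
                          confidence_floor=self.confidence_floor)


class MetricsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pck_alpha: float = 0.2
    torso_pair: tuple[str, str] = ("right_shoulder", "left_hip")

    def to_config(self) -> MetricConfig:
        return MetricConfig(pck_alpha=self.pck_alpha,
                            torso_pair=tuple(self.torso_pair))


class PipelineConfig(BaseModel):
    """Single document binding all stage settings; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    rotation_step: float = 10.0
    cost: CostConfig = CostConfig()
    metrics: MetricsConfig = MetricsConfig()
    selector: Literal["graph", "abg", "unrotated"] = "graph"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
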