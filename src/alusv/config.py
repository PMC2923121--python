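"""YAML configuration: ``mechanism``, ``mlpa`` and ``junction`` blocks."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .mechanism import MechanismParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class MlpaParams:
    lower: float = 0.75
    upper: float = 1.25


@dataclass(frozen=True)
class JunctionParams:
    min_anchor: int = 20
    max_mismatch: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    mechanism: MechanismParams = MechanismParams()
    mlpa: MlpaParams = MlpaParams()
    junction: JunctionParams = JunctionParams()


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load a YAML config; absent file/keys fall back to defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}

    def build(cls, block):
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(block) - known
        if extra:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(extra)}")
        return cls(**block)

    return PipelineConfig(
        mechanism=build(MechanismParams, data.get("mechanism", {})),
        mlpa=build(MlpaParams, data.get("mlpa", {})),
        junction=build(JunctionParams, data.get("junction", {})),
    )
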