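"""YAML pipeline configuration with strict validation.

Unknown keys are rejected.  The resolved configuration written next to a
run's artifacts records, for every field, whether the value was left at its
default or set by the user, so experiment provenance stays auditable.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulatorSection(_Strict):
    n_subjects_per_group: int = 30
    n_rois: int = 20
    n_timepoints: int = 232
    n_affected: int = 8
    self_coupling: float = 0.25
    cov_coupling: tuple[float, float] = (0.05, 0.25)
    lag_coupling: tuple[float, float] = (0.0, 0.3)
    noise_sd: float = Field(1.0, gt=0)


class FcnSection(_Strict):
    sr_lambda: float = Field(1.0, ge=0)
    sr_max_iterations: int = 500
    sr_tolerance: float = Field(1e-8, gt=0)
    lag_order: int = Field(1, ge=1)
    threshold_pc: float = Field(0.1, ge=0, lt=1)
    threshold_sr: float = Field(0.2, ge=0, lt=1)
    threshold_gcm: float = Field(0.2, ge=0, lt=1)

    def thresholds(self) -> dict[str, float]:
        return {"PC": self.threshold_pc, "SR": self.threshold_sr,
                "GCM": self.threshold_gcm}


class ModelSection(_Strict):
    conv_width: int = 32
    head_hidden: tuple[int, int] = (32, 16)
    dropout: float = Field(0.5, ge=0, lt=1)


class TrainingSection(_Strict):
    learning_rate: float = 0.0025
    weight_decay: float = 1e-5
    epochs: int = Field(150, ge=1)
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20
    k_folds: int = 5
    n_repetitions: int = 10
    patterns: list[Literal["PC", "SR", "GCM"]] = ["PC", "SR", "GCM"]


class InterpretationSection(_Strict):
    target_class: Literal[0, 1] = 1
    top_k: int = Field(5, ge=1)


class PipelineConfig(_Strict):
    simulator: SimulatorSection = SimulatorSection()
    fcn: FcnSection = FcnSection()
    model: ModelSection = ModelSection()
    training: TrainingSection = TrainingSection()
    interpretation: InterpretationSection = InterpretationSection()


def load_config(path: str | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def dump_resolved(cfg: PipelineConfig, path: str) -> None:
    """Write the fully resolved config with default/user provenance notes."""
    defaults = PipelineConfig().model_dump()
    resolved = cfg.model_dump()
    provenance = {
        section: {key: ("default" if resolved[section][key] == defaults[section][key]
                        else "user")
                  for key in resolved[section]}
        for section in resolved
    }
    with open(path, "w") as fh:
        yaml.safe_dump({"config": resolved, "provenance": provenance}, fh,
                       sort_keys=False)


def load_resolved(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.model_validate(data["config"])
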