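"""Run configuration: a validated YAML schema feeding every CLI command.

A single integer seed is fanned out to named substreams (simulation, weight
init, training shuffling) so a whole pipeline rerun is reproducible from one
number.  Every artifact the CLI writes records the configuration hash and
the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "seed_for"]


class SimulatorConfig(BaseModel):
    n_per_category: tuple[int, int, int, int] = (5, 5, 5, 5)
    duration_s: float = 28800.0
    ppg_fs: float = 256.0
    intrusion_duration_s: float = 15.0
    wake_intrusion_rate: dict[str, float] = Field(
        default_factory=lambda: {"no": 2.0, "mild": 8.0,
                                 "moderate": 20.0, "severe": 40.0})

    @field_validator("n_per_category")
    @classmethod
    def _positive_counts(cls, v):
        if any(n <= 0 for n in v):
            raise ValueError("category counts must be positive")
        return v


class TrainingConfig(BaseModel):
    lr_min: float = 1e-3
    lr_max: float = 1e-2
    ramp_epochs: int = 3
    tail_epochs: int = 20
    momentum: float = 0.9
    n_epochs: int | None = None
    compact: bool = True  # width-reduced architecture for CPU runs


class RunConfig(BaseModel):
    out_dir: Path = Path("ppgsleep_out")
    interval_s: int = 30
    n_classes: int = 5
    seed: int = 0
    channel: str = "PPG"
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)

    @field_validator("interval_s")
    @classmethod
    def _valid_interval(cls, v):
        if v not in (30, 15, 5, 1):
            raise ValueError("interval_s must be one of 30, 15, 5, 1")
        return v

    @field_validator("n_classes")
    @classmethod
    def _valid_classes(cls, v):
        if v not in (3, 4, 5):
            raise ValueError("n_classes must be 3, 4 or 5")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def seed_for(base_seed: int, stream: str) -> int:
    """Deterministic per-module substream seed below 2**31."""
    digest = hashlib.sha256(f"{base_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "little") >> 1
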