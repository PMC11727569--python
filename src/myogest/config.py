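"""Validated run configuration (YAML round-trip, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DataSection", "PreprocessSection", "ModelSection", "TrainSection",
    "RealtimeSection", "RunConfig", "load_config", "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Strict):
    path: Optional[str] = None
    format: str = "csv"
    f: Optional[float] = None

    @model_validator(mode="after")
    def _check_format(self):
        if self.format not in ("csv", "npz", "mat"):
            raise ValueError(f"unknown data format {self.format!r}")
        return self


class PreprocessSection(_Strict):
    filter_order: int = 4
    low_hz: float = 10.0
    high_hz: float = 500.0
    w_ms: float = 200.0
    s_ms: float = 50.0
    normalizer_scope: str = "train"  # or "all"
    keep_rest: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.normalizer_scope not in ("train", "all"):
            raise ValueError("normalizer_scope must be 'train' or 'all'")
        if not 0 < self.s_ms <= self.w_ms:
            raise ValueError("need 0 < s_ms <= w_ms")
        return self


class ModelSection(_Strict):
    n_classes: int = 6
    tau: int = 8
    dropout_p: float = 0.5
    attn_reduction_r: int = 8


class TrainSection(_Strict):
    variant: str = "full"
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    train_reps: List[int] = Field(default_factory=lambda: [1, 3, 4, 6])
    test_reps: List[int] = Field(default_factory=lambda: [2, 5])

    @model_validator(mode="after")
    def _check(self):
        if set(self.train_reps) & set(self.test_reps):
            raise ValueError("train_reps and test_reps overlap")
        return self


class RealtimeSection(_Strict):
    vote_window: int = 100
    map_commands: bool = True


class RunConfig(_Strict):
    seed: int = 0
    data: DataSection = Field(default_factory=DataSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    realtime: RealtimeSection = Field(default_factory=RealtimeSection)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
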