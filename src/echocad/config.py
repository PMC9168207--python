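"""Validated pipeline configuration (YAML-serializable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import CLASSIFIER_NAMES
from .transforms import METHODS


class SyntheticSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_normal: int = Field(51, ge=1)
    n_htn: int = Field(61, ge=1)


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    clip_limit: float = Field(0.01, gt=0, le=1)
    tiles: tuple[int, int] = (8, 8)


class LsdaParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_components: int = Field(30, ge=1)
    n_neighbors: int = Field(5, ge=1)
    alpha: float = Field(0.5, ge=0, le=1)
    ridge: float = Field(1e-6, ge=0)


class PipelineConfig(BaseModel):
    """Everything needed to reproduce a run: inputs, methods, seeds, mode."""

    model_config = ConfigDict(extra="forbid")

    source: Literal["synthetic", "directory"] = "synthetic"
    input_dir: Optional[str] = None
    synthetic: SyntheticSpec = SyntheticSpec()
    preprocess: PreprocessParams = PreprocessParams()
    methods: list[str] = Field(default=["cntlet", "shelet"], min_length=1)
    classifiers: list[str] = Field(default=list(CLASSIFIER_NAMES), min_length=1)
    lsda: LsdaParams = LsdaParams()
    n_folds: int = Field(10, ge=2)
    seed: int = 17
    mode: Literal["leakage_free", "paper_mode"] = "leakage_free"
    max_features: Optional[int] = None  # enable incremental selection when set
    output_dir: str = "echocad_run"

    def model_post_init(self, _ctx) -> None:
        for m in self.methods:
            if m not in METHODS and m != "crvlet":
                raise ValueError(f"unknown transform method {m!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {c!r}")
        if self.source == "directory" and not self.input_dir:
            raise ValueError("source 'directory' requires input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))
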