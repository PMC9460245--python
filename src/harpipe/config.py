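"""Validated run configuration for the command-line pipeline.

A single YAML file (plus CLI flag overrides) drives every stage; all
defaults match the library defaults, and every artifact is regenerable from
the config file and the root seed alone.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .evaluation import PipelineConfig
from .features import FeatureConfig


class SchemaConfig(BaseModel):
    subject: str = "subject"
    label: str = "label"
    timestamp: Optional[str] = "t"
    channels: list[str] = Field(default_factory=lambda: ["ch_0", "ch_1", "ch_2"])
    sample_rate_hz: float = 50.0
    layout: str = "wide"
    max_gap: int = 5

    def as_dict(self) -> dict:
        return self.model_dump()


class SegmentationConfig(BaseModel):
    median_kernel: int = 3
    window_seconds: float = 5.0
    overlap_fraction: float = Field(0.5, ge=0.0, lt=1.0)
    purity_threshold: float = Field(0.75, gt=0.0, le=1.0)

    @field_validator("median_kernel")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 != 1:
            raise ValueError("median_kernel must be odd")
        return v


class FeatureSettings(BaseModel):
    n_keep: int = Field(3, ge=1)
    haar_levels: int = Field(3, ge=1)
    wpe_levels: int = Field(2, ge=1)
    emd_max_imfs: int = Field(8, ge=1)
    emd_sd_stop: float = Field(0.2, gt=0.0)

    def to_feature_config(self) -> FeatureConfig:
        return FeatureConfig(**self.model_dump())


class SelectionConfig(BaseModel):
    learning_rate: float = Field(0.01, gt=0.0)
    batch_size: int = Field(1000, ge=1)
    max_epochs: int = Field(2000, ge=1)
    l2: float = Field(1e-4, ge=0.0)
    validation_fraction: float = Field(0.1, ge=0.0, lt=1.0)
    patience: int = Field(10, ge=1)
    k: float = 0.5


class ClassifierConfig(BaseModel):
    kind: str = "random_forest"
    n_trees: int = Field(100, ge=1)
    max_depth: Optional[int] = None

    @field_validator("kind")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in {"random_forest", "svm_rbf", "adaboost"}:
            raise ValueError(f"unknown classifier kind {v!r}")
        return v


class RunConfig(BaseModel):
    """Top-level configuration of one pipeline run."""

    data_schema: SchemaConfig = Field(default_factory=SchemaConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    features: FeatureSettings = Field(default_factory=FeatureSettings)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | None, overrides: dict | None = None) -> "RunConfig":
        raw: dict = {}
        if path is not None:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        for dotted, value in (overrides or {}).items():
            if value is None:
                continue
            cursor = raw
            *parents, leaf = dotted.split(".")
            for key in parents:
                cursor = cursor.setdefault(key, {})
            cursor[leaf] = value
        return cls.model_validate(raw)

    def to_pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            median_kernel=self.segmentation.median_kernel,
            window_seconds=self.segmentation.window_seconds,
            overlap_fraction=self.segmentation.overlap_fraction,
            purity_threshold=self.segmentation.purity_threshold,
            features=self.features.to_feature_config(),
            learning_rate=self.selection.learning_rate,
            batch_size=self.selection.batch_size,
            max_epochs=self.selection.max_epochs,
            l2=self.selection.l2,
            validation_fraction=self.selection.validation_fraction,
            patience=self.selection.patience,
            select_k=self.selection.k,
            classifier=self.classifier.kind,
            n_trees=self.classifier.n_trees,
            max_depth=self.classifier.max_depth,
            seed=self.seed,
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
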