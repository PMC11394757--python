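"""Structured pipeline configuration with strict YAML round-tripping.

Unknown keys are rejected (pydantic ``extra="forbid"``), so a typo in a
config file fails loudly with the offending key named.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .graphs import GraphConfig
from .pipeline import InferenceConfig, SurfaceConfig
from .training import TrainConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurfaceBlock(_Strict):
    probe_radius: float = 1.5
    target_density: float = 1.0
    scales: tuple = (1.0, 2.0, 3.5, 6.0, 10.0)
    label_threshold: float = 4.0
    chem_k: int = 16


class GraphBlock(_Strict):
    voxel_size: float = 1.0
    r0: float = 2.0
    r: float = 4.0
    max_edges: int = 32
    state_dim: int = 300


class ModelBlock(_Strict):
    classifier_dims: tuple = (128, 64)


class TrainBlock(_Strict):
    batch_size: int = 4
    lr: float = 5e-4
    weight_decay: float = 1e-5
    max_epochs: int = 50
    seed: int = 0
    pos_weight: float | str = "auto"
    early_stop_patience: int = 10


class InferenceBlock(_Strict):
    threshold: float = 0.5
    min_samples: int = 5
    max_eps: float = 6.0
    xi: float = 0.05


class EvaluationBlock(_Strict):
    dcc_threshold: float = 4.0
    dvo_voxel: float = 2.0


class PipelineConfig(_Strict):
    surface: SurfaceBlock = SurfaceBlock()
    graph: GraphBlock = GraphBlock()
    model: ModelBlock = ModelBlock()
    train: TrainBlock = TrainBlock()
    inference: InferenceBlock = InferenceBlock()
    evaluation: EvaluationBlock = EvaluationBlock()

    # -- conversions to the runtime dataclasses ---------------------------

    def surface_config(self) -> SurfaceConfig:
        return SurfaceConfig(**self.surface.model_dump())

    def graph_config(self) -> GraphConfig:
        return GraphConfig(**self.graph.model_dump())

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.train.model_dump())

    def inference_config(self) -> InferenceConfig:
        return InferenceConfig(**self.inference.model_dump())

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(_plain(self.model_dump())))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _plain(obj):
    """tuples -> lists so yaml stays clean."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
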