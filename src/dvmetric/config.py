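"""Validated YAML run configuration for the experiment runner.

The schema (pydantic models below) is the published contract of the CLI:
a ``data`` block (either a generator or a CSV path with a label column),
a ``model`` block, a ``fidelity`` block, the penalty ``lambda``, an
optional ``grid`` block for surface sweeps, and a global ``seed``.
Validation happens before any computation.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .data import LabeledDataset, read_dataset
from .datasets import (
    BlobConfig,
    ClusterSquareConfig,
    CubeRootConfig,
    make_blobs_dataset,
    make_cluster_square_dataset,
    make_cuberoot_dataset,
)
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_run_config", "build_dataset"]

_GENERATORS = {
    "blobs": (BlobConfig, make_blobs_dataset),
    "cuberoot": (CubeRootConfig, make_cuberoot_dataset),
    "cluster_square": (ClusterSquareConfig, make_cluster_square_dataset),
}


class GeneratorBlock(BaseModel):
    name: Literal["blobs", "cuberoot", "cluster_square"]
    params: dict = Field(default_factory=dict)


class CSVBlock(BaseModel):
    path: str
    label_column: Optional[str] = None
    label_kind: Optional[Literal["categorical", "continuous"]] = None


class DataBlock(BaseModel):
    generator: Optional[GeneratorBlock] = None
    csv: Optional[CSVBlock] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.generator is None) == (self.csv is None):
            raise ValueError("data block needs exactly one of "
                             "'generator' or 'csv'")
        return self


class ModelBlock(BaseModel):
    id: str
    mode: Optional[Literal["supervised", "unsupervised"]] = None
    hyperparams: dict = Field(default_factory=dict)


class FidelityBlock(BaseModel):
    beta: float = 0.1
    n_splits: int = 10
    train_fraction: float = 0.7
    split_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    estimator: Literal["plugin", "knn", "hash_ensemble"] = "hash_ensemble"
    estimator_params: dict = Field(default_factory=dict)
    mi_floor: float = 1e-3


class GridBlock(BaseModel):
    n_values: list[int]
    p_values: list[int]
    replicates: int = 5


class SelectionBlock(BaseModel):
    r: int


class RunConfig(BaseModel):
    """Top-level, schema-validated experiment configuration."""

    data: DataBlock
    model: ModelBlock
    fidelity: FidelityBlock = Field(default_factory=FidelityBlock)
    penalty: float = Field(default=0.01, alias="lambda")
    grid: Optional[GridBlock] = None
    selection: Optional[SelectionBlock] = None
    seed: int = 0

    model_config = {"populate_by_name": True}


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        raise ConfigError(f"invalid run configuration {path}: {exc}") from exc


def build_dataset(cfg: RunConfig, seed: int | None = None) -> LabeledDataset:
    """Materialize the dataset described by a run configuration."""
    block = cfg.data
    if block.csv is not None:
        return read_dataset(block.csv.path, block.csv.label_column,
                            block.csv.label_kind)
    gen = block.generator
    config_cls, factory = _GENERATORS[gen.name]
    params = dict(gen.params)
    if seed is not None:
        params.setdefault("seed", seed)
    return factory(config_cls(**params))
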