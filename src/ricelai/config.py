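"""Run configuration: schema-validated keys for the pipeline driver.

A run is described by a small YAML (or dict) configuration.  Unknown keys
are rejected up front so typos fail before any stage runs.  The ``paper``
profile uses the full published hyperparameters (e.g. 1000 DNN epochs);
the ``test`` profile caps ensemble sizes and epochs for desk-scale runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeasonSection(_Strict):
    t_base: float = 10.0
    gdd_senescence: float = 1200.0
    r_ref: float = 20.0
    season_length: int = 128


class NdviLaiSection(_Strict):
    alpha: float = 0.1
    beta: float = 4.0


class ModelSection(_Strict):
    family: str = "random_forest"
    hyperparameters: dict = Field(default_factory=dict)


class OptimizerSection(_Strict):
    ftol: float = 1e-8
    maxiter: int = 200


class SynthSection(_Strict):
    regions: list[str] = Field(default_factory=lambda: ["cheorwon", "paju"])
    n_pixels: int | None = None
    years: list[int] | None = None


class RunConfig(_Strict):
    """Top-level pipeline configuration."""

    out_dir: str = "runs"
    profile: Literal["paper", "test"] = "test"
    seed: int = 0
    train_fraction: float = 0.8
    season: SeasonSection = Field(default_factory=SeasonSection)
    ndvi_lai: NdviLaiSection = Field(default_factory=NdviLaiSection)
    model: ModelSection = Field(default_factory=ModelSection)
    optimizer: OptimizerSection = Field(default_factory=OptimizerSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    qa_bits: dict[int, int] = Field(default_factory=dict)

    @field_validator("train_fraction")
    @classmethod
    def _frac(cls, v):
        if not 0 < v < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        return v


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from YAML or a dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError -> package error type
        raise ConfigError(f"invalid run configuration: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration, stamped on every artifact.

    Output paths are excluded: the same scientific configuration written to
    two directories is the same run.
    """
    payload = config.model_dump(mode="json")
    payload.pop("out_dir", None)
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
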