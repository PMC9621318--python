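"""Pipeline configuration: validated blocks for every stage.

Defaults reproduce the published study conditions end to end; any block can
be overridden from a YAML file (see ``PipelineConfig.from_yaml``).  The seed
is the single source of randomness: every stage derives its own independent
stream from it, so a config fully determines the simulated data, the
cohort split and the scenario cohorts.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Literal

import yaml
from pydantic import BaseModel, Field, field_validator


class SimBlock(BaseModel):
    n_per_scenario_a: int = Field(5000, gt=0)
    n_per_combo_b: int = Field(2000, gt=0)
    css_max: float = Field(150.0, gt=0)


class FusionBlock(BaseModel):
    k_neighbors: int = Field(5, ge=1)
    impute_include_css: bool = True
    scaler_mode: Literal["full", "derivation"] = "full"
    split_fraction: float = Field(0.8, gt=0, lt=1)


class TrainingBlock(BaseModel):
    models: List[str] = ["xgboost", "random_forest", "bagging",
                         "gradient_boosting", "decision_tree", "adaboost",
                         "linear"]
    folds: int = Field(10, ge=2)
    final_model: str = "xgboost"
    hyperparams: Dict[str, object] = {}


class InterpretBlock(BaseModel):
    background_size: int = Field(512, ge=1)
    n_samples: int = Field(1000, ge=1)


class ScenarioBlock(BaseModel):
    n_patients: int = Field(1000, gt=0)
    n_times: int = Field(200, ge=2)


class ExternalBlock(BaseModel):
    bsv_cl_cv: float = Field(0.30, ge=0)
    residual_cv: float = Field(0.20, ge=0)


class PipelineConfig(BaseModel):
    seed: int = 0
    sim: SimBlock = SimBlock()
    fusion: FusionBlock = FusionBlock()
    training: TrainingBlock = TrainingBlock()
    interpret: InterpretBlock = InterpretBlock()
    scenarios: ScenarioBlock = ScenarioBlock()
    external: ExternalBlock = ExternalBlock()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Short stable hash embedded in every artifact for provenance."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
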