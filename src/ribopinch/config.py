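"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantsConfig(_Strict):
    R_kcal: float = 1.98720e-3
    calorie_J: float = 4.184


class ConditionConfig(_Strict):
    temperature: float = 310.15
    pH: float = 7.5
    monovalent_mM: float = 150.0
    mg_mM: float = 1.0


class BaselineConfig(_Strict):
    mode: Literal["constant", "parameterized"] = "constant"
    k_ref_per_s: float = 2e-10
    config_file: Optional[str] = None  # YAML with a full UncatModel spec


class FittingConfig(_Strict):
    model: Literal["auto", "mono", "bi"] = "auto"
    criterion: Literal["aicc", "ftest"] = "aicc"
    f_test_alpha: float = 0.05
    fix_plateau: Optional[float] = None
    amplitudes_sum_to_one: bool = False
    n_starts: int = Field(default=7, ge=5)
    time_unit: Optional[Literal["s", "min", "h"]] = None


class CouplingConfig(_Strict):
    group_by_linker: bool = False
    hinge: bool = True
    hinge_grid_step: float = 0.1
    exclude_wildtype: bool = True


class PathsConfig(_Strict):
    timecourses: Optional[str] = None
    titration: Optional[str] = None
    constructs: Optional[str] = None  # panel CSV with stabilities
    helices_fasta: Optional[str] = None
    outdir: str = "ribopinch_out"


class PipelineConfig(_Strict):
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    condition: ConditionConfig = Field(default_factory=ConditionConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except PydanticValidationError as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
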