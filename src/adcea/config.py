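"""Run configuration: schema, loading, dumping and hashing.

A run configuration nests every model parameter block plus the cohort
recipe, scenario list and one-time-treatment sweep.  YAML is the canonical
format; JSON is accepted.  An empty file resolves to the full defaults.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cea import ScenarioSpec, builtin_scenarios
from .cohort import CohortConfig
from .costs import CostTable, DrugPricing
from .errors import ConfigurationError
from .hazards import InstitutionalizationParams, MortalityParams
from .progression import ProgressionParams
from .utility import UtilityModel

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash", "default_config"]


class RunConfig(BaseModel):
    """Top-level configuration for a full analysis run.

    ``n`` and ``seed`` are authoritative for runs and override the values
    inside ``cohort``.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 12345
    n: int = Field(default=10_000, ge=1)
    max_age: float = Field(default=105.0, gt=0)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    progression: ProgressionParams = Field(default_factory=ProgressionParams)
    mortality: MortalityParams = Field(default_factory=MortalityParams)
    institutionalization: InstitutionalizationParams = Field(
        default_factory=InstitutionalizationParams
    )
    utilities: UtilityModel = Field(default_factory=UtilityModel)
    costs: CostTable = Field(default_factory=CostTable)
    pricing: DrugPricing = Field(default_factory=DrugPricing)
    scenarios: list[ScenarioSpec] = Field(default_factory=builtin_scenarios)
    onetime_prices: list[float] = Field(default_factory=lambda: [100_000.0, 250_000.0])
    onetime_effect_scales: list[float] = Field(default_factory=lambda: [1.0, 2.0])

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if any(p < 0 for p in self.onetime_prices):
            raise ValueError("onetime_prices must be >= 0")
        if any(s < 0 for s in self.onetime_effect_scales):
            raise ValueError("onetime_effect_scales must be >= 0")
        return self


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML/JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"top level of {path} must be a mapping")
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({paths})") from exc
    if cfg.pricing.mode == "one_time" and cfg.pricing.annual_price != 0:
        warnings.warn(
            "pricing.mode is 'one_time' but pricing.annual_price is non-zero; "
            "the annual price is ignored in one-time mode",
            stacklevel=2,
        )
    return cfg


def dump_config(config: RunConfig) -> str:
    """Serialize a config to canonical YAML (dump -> load is the identity)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the config."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
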