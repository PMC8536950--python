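"""Synthetic baseline cohorts with the structure of an MCI trial population.

Every generated patient enters in mild cognitive impairment with MMSE in
24-30.  Distributional defaults are documented assumptions (no baseline
table is available to copy), all overridable through :class:`CohortConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator
from scipy import stats

from .errors import CohortParseError, ConfigurationError

__all__ = ["PatientBaseline", "CohortConfig", "generate_cohort", "read_cohort", "write_cohort"]

MMSE_SCORES = (24, 25, 26, 27, 28, 29, 30)

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "mmse0",
    "cdrsb0",
    "npi0",
    "has_caregiver",
    "caregiver_age",
]


@dataclass(frozen=True, slots=True)
class PatientBaseline:
    """One simulated person's state at model entry."""

    id: int
    age: float
    sex: str  # "female" | "male"
    mmse0: int
    cdrsb0: float
    npi0: float
    has_caregiver: bool
    caregiver_age: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 0 <= self.mmse0 <= 30:
            raise ConfigurationError(f"mmse0 out of range [0, 30]: {self.mmse0}")
        if not 0.0 <= self.cdrsb0 <= 18.0:
            raise ConfigurationError(f"cdrsb0 out of range [0, 18]: {self.cdrsb0}")
        if self.npi0 < 0.0:
            raise ConfigurationError(f"npi0 must be >= 0: {self.npi0}")


class CohortConfig(BaseModel):
    """Distributional parameters for baseline cohort generation."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=1000, ge=1)
    seed: int = 0
    age_mean: float = 73.0
    age_sd: float = Field(default=7.0, ge=0)
    age_bounds: tuple[float, float] = (55.0, 90.0)
    prop_female: float = Field(default=0.45, ge=0, le=1)
    #: Probabilities over MMSE scores 24..30, in that order.
    mmse_weights: tuple[float, ...] = tuple([1.0 / 7.0] * 7)
    cdrsb_mean: float = 1.5
    cdrsb_sd: float = Field(default=1.0, ge=0)
    cdrsb_bounds: tuple[float, float] = (0.5, 4.0)
    npi_mean: float = 3.0
    npi_sd: float = Field(default=3.0, ge=0)
    prop_with_caregiver: float = Field(default=1.0, ge=0, le=1)
    caregiver_age_offset: float = -3.0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if len(self.mmse_weights) != len(MMSE_SCORES):
            raise ValueError(
                f"mmse_weights must have {len(MMSE_SCORES)} entries (scores 24..30), "
                f"got {len(self.mmse_weights)}"
            )
        if any(w < 0 for w in self.mmse_weights):
            raise ValueError("mmse_weights must be non-negative")
        if not math.isclose(sum(self.mmse_weights), 1.0, abs_tol=1e-9):
            raise ValueError(f"mmse_weights must sum to 1, got {sum(self.mmse_weights)!r}")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise ValueError(f"age_bounds must be increasing, got {self.age_bounds}")
        if self.cdrsb_bounds[0] >= self.cdrsb_bounds[1]:
            raise ValueError(f"cdrsb_bounds must be increasing, got {self.cdrsb_bounds}")
        if not 0.0 <= self.cdrsb_bounds[0] or self.cdrsb_bounds[1] > 18.0:
            raise ValueError(f"cdrsb_bounds must lie within [0, 18], got {self.cdrsb_bounds}")
        return self


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    if sd == 0:
        return np.full(n, min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[PatientBaseline]:
    """Draw ``config.n`` baseline patients, deterministically for a given seed."""
    if not isinstance(config, CohortConfig):
        try:
            config = CohortConfig.model_validate(config)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc
    rng = np.random.default_rng(config.seed)
    n = config.n
    age = _truncated_normal(rng, n, config.age_mean, config.age_sd, *config.age_bounds)
    female = rng.random(n) < config.prop_female
    mmse = rng.choice(np.array(MMSE_SCORES), size=n, p=np.asarray(config.mmse_weights))
    cdrsb = _truncated_normal(rng, n, config.cdrsb_mean, config.cdrsb_sd, *config.cdrsb_bounds)
    npi = _truncated_normal(rng, n, config.npi_mean, config.npi_sd, 0.0, np.inf)
    has_cg = rng.random(n) < config.prop_with_caregiver
    return [
        PatientBaseline(
            id=i,
            age=float(age[i]),
            sex="female" if female[i] else "male",
            mmse0=int(mmse[i]),
            cdrsb0=float(cdrsb[i]),
            npi0=float(npi[i]),
            has_caregiver=bool(has_cg[i]),
            caregiver_age=float(age[i] + config.caregiver_age_offset),
        )
        for i in range(n)
    ]


def write_cohort(cohort: Sequence[PatientBaseline], path) -> None:
    """Write a cohort to CSV (UTF-8, '.' decimal separator)."""
    df = pd.DataFrame([vars_of(p) for p in cohort], columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)


def vars_of(p: PatientBaseline) -> dict:
    return {
        "id": p.id,
        "age": p.age,
        "sex": p.sex,
        "mmse0": p.mmse0,
        "cdrsb0": p.cdrsb0,
        "npi0": p.npi0,
        "has_caregiver": p.has_caregiver,
        "caregiver_age": p.caregiver_age,
    }


def read_cohort(path) -> list[PatientBaseline]:
    """Read a cohort CSV, validating each row; errors carry row and field."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError("no records") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise CohortParseError("no records")
    out: list[PatientBaseline] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hc = row.has_caregiver
            if isinstance(hc, str):
                hc = hc.strip().lower() in ("true", "1", "yes")
            out.append(
                PatientBaseline(
                    id=int(row.id),
                    age=float(row.age),
                    sex=str(row.sex),
                    mmse0=int(row.mmse0),
                    cdrsb0=float(row.cdrsb0),
                    npi0=float(row.npi0),
                    has_caregiver=bool(hc),
                    caregiver_age=float(row.caregiver_age),
                )
            )
        except (ConfigurationError, ValueError) as exc:
            raise CohortParseError(str(exc), row=i) from exc
    return out
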