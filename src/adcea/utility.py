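"""Health-state utilities for patients and caregivers, and QALY accrual.

Patient utility is an additive EQ-5D-style regression in current cognition,
behaviour, institutionalization and living-with-caregiver status, clamped to
[0, 1].  (The source table prints the regression with spurious "x" signs
between terms; the additive linear reading implemented here is the standard
one for such published EQ-5D models.)  Caregiver utility is a lookup: 1.00
while the patient has MCI, a band value by patient MMSE in dementia, and the
age-specific population norm once the patient is institutionalized or dead.
"""

from __future__ import annotations

import bisect
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, ContractViolationError
from .progression import Location, PatientState, Stage

__all__ = [
    "CaregiverDementiaUtilities",
    "UtilityModel",
    "patient_utility",
    "caregiver_utility",
    "accrue_qalys",
    "load_population_norms",
]


def load_population_norms(path=None) -> tuple[tuple[float, float], ...]:
    """Load (age_lower, utility) norm bands from CSV; bundled file by default."""
    if path is None:
        with resources.as_file(resources.files("adcea.data") / "population_norms.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"age_lower", "utility"}.issubset(df.columns):
        raise ConfigurationError("population norms CSV needs columns age_lower, utility")
    rows = sorted((float(r.age_lower), float(r.utility)) for r in df.itertuples(index=False))
    return tuple(rows)


class CaregiverDementiaUtilities(BaseModel):
    """Caregiver utility by the patient's MMSE band while in dementia."""

    model_config = ConfigDict(extra="forbid")

    mmse_21_plus: float = Field(default=0.85, ge=0, le=1)
    mmse_15_20: float = Field(default=0.84, ge=0, le=1)
    mmse_0_14: float = Field(default=0.82, ge=0, le=1)

    @model_validator(mode="after")
    def _decreasing(self) -> "CaregiverDementiaUtilities":
        if not self.mmse_21_plus > self.mmse_15_20 > self.mmse_0_14:
            raise ValueError(
                "caregiver dementia utilities must strictly decrease with worsening band"
            )
        return self

    def for_mmse(self, mmse: float) -> float:
        if mmse >= 21.0:
            return self.mmse_21_plus
        if mmse >= 15.0:
            return self.mmse_15_20
        return self.mmse_0_14


class UtilityModel(BaseModel):
    """Patient utility regression plus caregiver utility schedule."""

    model_config = ConfigDict(extra="forbid")

    intercept: float = 0.408
    coef_mmse: float = 0.010
    coef_npi: float = -0.04
    coef_institutionalized: float = -0.159
    coef_lives_with_caregiver: float = 0.051
    caregiver_mci_utility: float = Field(default=1.00, ge=0, le=1)
    caregiver_dementia_utility: CaregiverDementiaUtilities = Field(
        default_factory=CaregiverDementiaUtilities
    )
    #: (age_lower, utility) bands for the caregiver population-norm reset.
    population_norm_by_age: tuple[tuple[float, float], ...] = Field(
        default_factory=load_population_norms
    )

    @model_validator(mode="after")
    def _norms_valid(self) -> "UtilityModel":
        if not self.population_norm_by_age:
            raise ValueError("population_norm_by_age must not be empty")
        for lo, u in self.population_norm_by_age:
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"population norm utility out of [0, 1]: {u} (age {lo})")
        return self

    def population_norm(self, age: float) -> float:
        lowers = [lo for lo, _ in self.population_norm_by_age]
        i = max(bisect.bisect_right(lowers, age) - 1, 0)
        return self.population_norm_by_age[i][1]


def patient_utility(state: PatientState, model: UtilityModel) -> float:
    """Current-cycle patient utility weight, clamped to [0, 1]."""
    if not state.alive:
        raise ContractViolationError("patient_utility called on a dead patient")
    u = model.intercept + model.coef_mmse * state.mmse + model.coef_npi * state.npi
    if state.location is Location.RESIDENTIAL:
        u += model.coef_institutionalized
    elif state.has_caregiver:
        u += model.coef_lives_with_caregiver
    return min(1.0, max(0.0, u))


def caregiver_utility(state: PatientState, caregiver_age: float, model: UtilityModel) -> float:
    """Caregiver utility this cycle.

    Reverts to the age-specific population norm when the patient is
    institutionalized or dead; otherwise 1.00 in MCI and the dementia band
    value by the patient's current MMSE.
    """
    if not state.alive or state.location is Location.RESIDENTIAL:
        return model.population_norm(caregiver_age)
    if state.stage is Stage.MCI:
        return model.caregiver_mci_utility
    return model.caregiver_dementia_utility.for_mmse(state.mmse)


def accrue_qalys(
    utility_stream: Iterable[tuple[int, float]] | Sequence[tuple[int, float]],
    discount_rate: float,
    cycle_length_months: float = 1.0,
) -> float:
    """Discounted QALYs from a stream of (cycle index, utility weight).

    ``QALY = sum w_t * (cycle_length/12) * (1 + rate)^(-t*cycle_length/12)``.
    """
    if discount_rate < 0:
        raise ConfigurationError(f"discount_rate must be >= 0, got {discount_rate}")
    frac = cycle_length_months / 12.0
    base = 1.0 + discount_rate
    return sum(w * frac * base ** (-t * frac) for t, w in utility_stream)
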