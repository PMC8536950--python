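"""Per-cycle mortality and community-to-residential transition hazards.

Mortality starts from an age/sex life table and is adjusted by a
proportional-hazards factor in current cognition, the trailing annual rate
of MMSE decline, and baseline cognition.  Institutionalization risk is a
stage-specific base monthly rate scaled log-linearly in time-at-stage and
age, with a sex rate ratio; residential care is absorbing.

The bundled life table is a smooth Gompertz-like placeholder, not a
national statistic; both it and all coefficients are config-overridable.
"""

from __future__ import annotations

import bisect
import math
from importlib import resources

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, PrivateAttr

from .cohort import PatientBaseline
from .errors import ConfigurationError, ContractViolationError
from .progression import Location, PatientState, StageValues

__all__ = [
    "LifeTable",
    "MortalityParams",
    "InstitutionalizationParams",
    "mortality_probability",
    "institutionalization_probability",
]


class LifeTable:
    """Annual death probabilities by age band and sex."""

    def __init__(self, bands: dict[str, list[tuple[float, float]]]):
        for sex in ("female", "male"):
            if sex not in bands or not bands[sex]:
                raise ConfigurationError(f"life table missing rows for sex '{sex}'")
        self._lowers: dict[str, list[float]] = {}
        self._qs: dict[str, list[float]] = {}
        for sex, rows in bands.items():
            rows = sorted(rows)
            for _, q in rows:
                if not 0.0 <= q <= 1.0:
                    raise ConfigurationError(f"life table probability out of [0, 1]: {q}")
            self._lowers[sex] = [r[0] for r in rows]
            self._qs[sex] = [r[1] for r in rows]

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        required = {"age_lower", "sex", "annual_q"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"life table CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        bands: dict[str, list[tuple[float, float]]] = {"female": [], "male": []}
        for row in df.itertuples(index=False):
            bands.setdefault(str(row.sex), []).append((float(row.age_lower), float(row.annual_q)))
        return cls(bands)

    @classmethod
    def bundled(cls) -> "LifeTable":
        with resources.as_file(resources.files("adcea.data") / "life_table.csv") as p:
            return cls.from_csv(p)

    def annual_q(self, age: float, sex: str) -> float:
        """Annual death probability for the band containing ``age``."""
        lowers = self._lowers[sex]
        i = bisect.bisect_right(lowers, age) - 1
        i = max(i, 0)
        return self._qs[sex][i]


class MortalityParams(BaseModel):
    """Log-hazard coefficients on top of the life table.

    Placeholder magnitudes for an unpublished survival regression; they keep
    the stated covariate set (age, sex via the table; current and baseline
    cognition; decline rate) with transparent, overridable values.
    """

    model_config = ConfigDict(extra="forbid")

    #: Log-hazard per point of (30 - current MMSE).
    beta_mmse: float = 0.002
    #: Log-hazard per (MMSE point/year) of trailing annual decline.
    beta_decline: float = 0.005
    #: Log-hazard per point of (30 - baseline MMSE).
    beta_baseline_mmse: float = 0.01
    #: Path to a life-table CSV; None loads the bundled table.
    life_table_path: str | None = None

    _table: LifeTable | None = PrivateAttr(default=None)

    def life_table(self) -> LifeTable:
        if self._table is None:
            self._table = (
                LifeTable.bundled()
                if self.life_table_path is None
                else LifeTable.from_csv(self.life_table_path)
            )
        return self._table


class InstitutionalizationParams(BaseModel):
    """Monthly community-to-residential transition rates and adjusters."""

    model_config = ConfigDict(extra="forbid")

    base_monthly_rate_by_stage: StageValues = Field(
        default_factory=lambda: StageValues(mci=0.001, mild=0.001, moderate=0.001, severe=0.001)
    )
    #: Log-rate slope per month already spent in the current stage.
    gamma_time_in_stage: float = 0.002
    #: Log-rate slope per year of age over the reference age.
    gamma_age: float = 0.03
    reference_age: float = 75.0
    female_multiplier: float = Field(default=1.1, gt=0)


def mortality_probability(
    state: PatientState,
    baseline: PatientBaseline,
    params: MortalityParams,
    cycle_length_months: float = 1.0,
) -> float:
    """Per-cycle death probability.

    ``p = 1 - (1 - q)**(HR * cycle_length/12)`` with the life-table annual
    probability ``q`` for the patient's current age/sex, and
    ``HR = exp(beta_mmse*(30-mmse) + beta_decline*decline + beta_baseline_mmse*(30-mmse0))``.
    """
    if not state.alive:
        raise ContractViolationError("mortality_probability called on a dead patient")
    q = params.life_table().annual_q(state.age, baseline.sex)
    hr = math.exp(
        params.beta_mmse * (30.0 - state.mmse)
        + params.beta_decline * state.annual_mmse_decline
        + params.beta_baseline_mmse * (30.0 - baseline.mmse0)
    )
    p = 1.0 - (1.0 - q) ** (hr * cycle_length_months / 12.0)
    return min(1.0, max(0.0, p))


def institutionalization_probability(
    state: PatientState,
    baseline: PatientBaseline,
    params: InstitutionalizationParams,
    cycle_length_months: float = 1.0,
) -> float:
    """Per-cycle probability of moving from community to residential care."""
    if not state.alive:
        raise ContractViolationError("institutionalization_probability called on a dead patient")
    if state.location is not Location.COMMUNITY:
        raise ContractViolationError(
            "institutionalization_probability called on a residential patient"
        )
    rate = params.base_monthly_rate_by_stage.for_stage(state.stage) * cycle_length_months
    rate *= math.exp(
        params.gamma_time_in_stage * state.months_in_stage
        + params.gamma_age * (state.age - params.reference_age)
    )
    if baseline.sex == "female":
        rate *= params.female_multiplier
    return min(1.0, max(0.0, rate))
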