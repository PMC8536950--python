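"""Cognitive/behavioural disease progression, severity staging and treatment rules.

The progression engine advances CDR-SB (Clinical Dementia Rating - Sum of
Boxes, 0-18, higher = worse) with stage-specific constant annual rates, and
drives MMSE (Mini-Mental State Examination, 0-30, higher = better) through a
linear coupling to the CDR-SB increment.  A disease-modifying treatment is
modelled as a proportional reduction of the CDR-SB change rate while the
patient is on drug; drug exposure ends either through an annual
discontinuation hazard or through a stopping rule triggered at a configurable
severity stage, with no residual benefit afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum, IntEnum

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ContractViolationError

__all__ = [
    "Stage",
    "Location",
    "StageValues",
    "ProgressionParams",
    "PatientState",
    "assign_severity",
    "step_progression",
    "cycle_discontinuation_probability",
    "sample_discontinuation",
    "apply_stopping_rule",
]

CDRSB_MAX = 18.0
MMSE_MAX = 30.0


class Stage(IntEnum):
    """Disease severity stage, ordered from least to most severe."""

    MCI = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


class Location(str, Enum):
    COMMUNITY = "community"
    RESIDENTIAL = "residential"


class StageValues(BaseModel):
    """A scalar quantity defined per severity stage."""

    model_config = ConfigDict(extra="forbid")

    mci: float
    mild: float
    moderate: float
    severe: float

    def for_stage(self, stage: Stage) -> float:
        return (self.mci, self.mild, self.moderate, self.severe)[int(stage)]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mci, self.mild, self.moderate, self.severe)


class ProgressionParams(BaseModel):
    """Parameters of the per-cycle progression and treatment model.

    Defaults are transparent, overridable placeholders for the proprietary
    longitudinal regression coefficients they stand in for; the
    stage-dependence of the annual change rates represents the switch to
    faster decline at advanced severity.
    """

    model_config = ConfigDict(extra="forbid")

    cycle_length_months: float = Field(default=1.0, gt=0)
    annual_cdrsb_change_by_stage: StageValues = Field(
        default_factory=lambda: StageValues(mci=1.0, mild=1.6, moderate=2.0, severe=2.0)
    )
    annual_npi_change_by_stage: StageValues = Field(
        default_factory=lambda: StageValues(mci=0.5, mild=1.5, moderate=1.5, severe=1.5)
    )
    #: MMSE points lost per CDR-SB point gained (linear coupling).
    mmse_per_cdrsb: float = Field(default=1.6, ge=0)
    #: CDR-SB level at which MCI converts to dementia (stays converted).
    conversion_cdrsb_threshold: float = Field(default=4.5, gt=0)
    #: Proportional reduction of the CDR-SB change rate while on drug.
    treatment_effect: float = Field(default=0.25, ge=0, le=1)
    #: Annual probability of discontinuing the drug.
    annual_discontinuation: float = Field(default=0.10, ge=0, lt=1)
    #: Severity stage at (or beyond) which the drug is stopped.
    stop_stage: Stage = Stage.MODERATE
    residual_benefit: bool = False

    @model_validator(mode="after")
    def _rates_nonnegative(self) -> "ProgressionParams":
        for name in ("annual_cdrsb_change_by_stage", "annual_npi_change_by_stage"):
            vals = getattr(self, name)
            for stage_name, v in vals.model_dump().items():
                if v < 0:
                    raise ValueError(f"{name}.{stage_name} must be >= 0, got {v}")
        return self


@dataclass(slots=True)
class PatientState:
    """Time-evolving record of one simulated patient."""

    cycle: int
    age: float
    mmse: float
    cdrsb: float
    npi: float
    stage: Stage
    location: Location
    alive: bool
    on_treatment: bool
    months_in_stage: float
    converted: bool
    has_caregiver: bool
    #: Trailing 12-month MMSE loss; 0.0 during the first simulated year.
    annual_mmse_decline: float = 0.0

    def copy(self) -> "PatientState":
        return replace(self)


def assign_severity(mmse: float, converted_to_dementia: bool) -> Stage:
    """Stage a patient from cognition alone.

    Pre-conversion patients are MCI regardless of MMSE; after conversion the
    MMSE bands are mild (>= 21), moderate ([15, 21)), severe (< 15).
    """
    if not 0.0 <= mmse <= MMSE_MAX:
        raise ContractViolationError(f"mmse out of range [0, 30]: {mmse}")
    if not converted_to_dementia:
        return Stage.MCI
    if mmse >= 21.0:
        return Stage.MILD
    if mmse >= 15.0:
        return Stage.MODERATE
    return Stage.SEVERE


def step_progression(
    state: PatientState, params: ProgressionParams, on_drug: bool
) -> PatientState:
    """Advance one cycle of cognitive/behavioural decline.

    The CDR-SB increment for the cycle is the stage-specific annual rate
    scaled to the cycle length, reduced by ``treatment_effect`` while on
    drug.  MMSE moves by ``-mmse_per_cdrsb`` times the nominal CDR-SB
    increment (so cognition keeps declining even after CDR-SB saturates at
    18), and both scores are clamped to their scale bounds.  NPI progresses
    at the untreated stage rate; the treatment effect does not touch it.
    """
    if not state.alive:
        raise ContractViolationError("step_progression called on a dead patient")
    cl = params.cycle_length_months
    frac = cl / 12.0
    inc = params.annual_cdrsb_change_by_stage.for_stage(state.stage) * frac
    if on_drug:
        inc *= 1.0 - params.treatment_effect
    cdrsb = min(CDRSB_MAX, max(0.0, state.cdrsb + inc))
    mmse = min(MMSE_MAX, max(0.0, state.mmse - params.mmse_per_cdrsb * inc))
    npi = max(0.0, state.npi + params.annual_npi_change_by_stage.for_stage(state.stage) * frac)
    converted = state.converted or cdrsb >= params.conversion_cdrsb_threshold
    stage = assign_severity(mmse, converted)
    months = state.months_in_stage + cl if stage == state.stage else 0.0
    return PatientState(
        cycle=state.cycle + 1,
        age=state.age + frac,
        mmse=mmse,
        cdrsb=cdrsb,
        npi=npi,
        stage=stage,
        location=state.location,
        alive=True,
        on_treatment=state.on_treatment,
        months_in_stage=months,
        converted=converted,
        has_caregiver=state.has_caregiver,
        annual_mmse_decline=state.annual_mmse_decline,
    )


def cycle_discontinuation_probability(params: ProgressionParams) -> float:
    """Per-cycle discontinuation probability implied by the annual rate.

    Converts with constant-hazard compounding so that twelve monthly cycles
    reproduce the annual probability exactly:
    ``p = 1 - (1 - annual)**(cycle_length/12)``.
    """
    return 1.0 - (1.0 - params.annual_discontinuation) ** (params.cycle_length_months / 12.0)


def sample_discontinuation(params: ProgressionParams, rng_draw: float) -> bool:
    """True iff the uniform draw falls below the per-cycle discontinuation probability."""
    return rng_draw < cycle_discontinuation_probability(params)


def apply_stopping_rule(state: PatientState, params: ProgressionParams) -> PatientState:
    """Turn treatment off once the stopping stage is reached (idempotent, in place)."""
    if state.on_treatment and state.stage >= params.stop_stage:
        state.on_treatment = False
    return state
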