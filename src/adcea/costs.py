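"""Monthly cost components by severity stage, drug pricing, and accrual.

Cost defaults are the published per-stage monthly figures (US $/month) for
patient health care, patient non-health-care, caregiver health care and
caregiver productivity.  Caregiver components stop at institutionalization,
mirroring the caregiver utility reset; patient non-health-care costs (which
include dependent living accommodation) continue.  The drug is priced either
per year while on treatment or as a single charge at initiation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, ContractViolationError
from .progression import Location, PatientState, StageValues

__all__ = [
    "CostTable",
    "DrugPricing",
    "CostBreakdown",
    "COST_COMPONENTS",
    "cycle_costs",
    "one_time_charge",
    "accrue_costs",
]

COST_COMPONENTS = (
    "drug",
    "patient_healthcare",
    "patient_nonhealthcare",
    "caregiver_healthcare",
    "caregiver_productivity",
)


class CostTable(BaseModel):
    """Monthly cost (US $) per component and severity stage."""

    model_config = ConfigDict(extra="forbid")

    patient_healthcare: StageValues = Field(
        default_factory=lambda: StageValues(mci=1174, mild=1377, moderate=1833, severe=2105)
    )
    patient_nonhealthcare: StageValues = Field(
        default_factory=lambda: StageValues(mci=207, mild=384, moderate=611, severe=1025)
    )
    caregiver_healthcare: StageValues = Field(
        default_factory=lambda: StageValues(mci=705, mild=731, moderate=748, severe=759)
    )
    caregiver_productivity: StageValues = Field(
        default_factory=lambda: StageValues(mci=925, mild=2044, moderate=3019, severe=5055)
    )

    @model_validator(mode="after")
    def _check(self) -> "CostTable":
        for name in (
            "patient_healthcare",
            "patient_nonhealthcare",
            "caregiver_healthcare",
            "caregiver_productivity",
        ):
            vals = getattr(self, name).as_tuple()
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} costs must be >= 0")
        for name in ("patient_healthcare", "caregiver_productivity"):
            vals = getattr(self, name).as_tuple()
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing with severity")
        return self


class DrugPricing(BaseModel):
    """How the hypothetical drug is priced."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["repeated", "one_time"] = "repeated"
    annual_price: float = Field(default=16_000.0, ge=0)
    one_time_price: float = Field(default=100_000.0, ge=0)
    #: Multiplier on the base-case treatment effect (scenario sweeps).
    effect_scale: float = Field(default=1.0, ge=0)


@dataclass(slots=True)
class CostBreakdown:
    """Costs (US $) split by component; ``total`` is always their sum."""

    drug: float = 0.0
    patient_healthcare: float = 0.0
    patient_nonhealthcare: float = 0.0
    caregiver_healthcare: float = 0.0
    caregiver_productivity: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.drug
            + self.patient_healthcare
            + self.patient_nonhealthcare
            + self.caregiver_healthcare
            + self.caregiver_productivity
        )

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            *(getattr(self, f.name) + getattr(other, f.name) for f in fields(self))
        )

    def __sub__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            *(getattr(self, f.name) - getattr(other, f.name) for f in fields(self))
        )

    def scaled(self, factor: float) -> "CostBreakdown":
        return CostBreakdown(*(getattr(self, f.name) * factor for f in fields(self)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def cycle_costs(
    state: PatientState,
    table: CostTable,
    pricing: DrugPricing,
    cycle_length_months: float = 1.0,
) -> CostBreakdown:
    """Undiscounted costs incurred during one cycle in the given state.

    Caregiver components are zero once the patient is residential (the
    informal caregiver steps back) or when the patient has no caregiver.
    The per-cycle drug charge applies only in repeated pricing mode while on
    treatment; one-time pricing is charged separately at initiation.
    """
    if not state.alive:
        raise ContractViolationError("cycle_costs called on a dead patient")
    stage = state.stage
    cl = cycle_length_months
    residential = state.location is Location.RESIDENTIAL
    caregiver_active = state.has_caregiver and not residential
    drug = 0.0
    if state.on_treatment and pricing.mode == "repeated":
        drug = pricing.annual_price * cl / 12.0
    return CostBreakdown(
        drug=drug,
        patient_healthcare=table.patient_healthcare.for_stage(stage) * cl,
        patient_nonhealthcare=table.patient_nonhealthcare.for_stage(stage) * cl,
        caregiver_healthcare=table.caregiver_healthcare.for_stage(stage) * cl
        if caregiver_active
        else 0.0,
        caregiver_productivity=table.caregiver_productivity.for_stage(stage) * cl
        if caregiver_active
        else 0.0,
    )


def one_time_charge(pricing: DrugPricing) -> float:
    """Full one-time drug price, charged at cycle 0 in the treatment arm only."""
    if pricing.mode != "one_time":
        raise ContractViolationError("one_time_charge called in repeated pricing mode")
    return pricing.one_time_price


def accrue_costs(
    stream: Iterable[tuple[int, CostBreakdown]],
    discount_rate: float,
    cycle_length_months: float = 1.0,
) -> CostBreakdown:
    """Component-wise discounted sum of per-cycle cost increments."""
    if discount_rate < 0:
        raise ConfigurationError(f"discount_rate must be >= 0, got {discount_rate}")
    frac = cycle_length_months / 12.0
    base = 1.0 + discount_rate
    out = CostBreakdown()
    for t, inc in stream:
        out = out + inc.scaled(base ** (-t * frac))
    return out
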