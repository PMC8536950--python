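"""Paired microsimulation and incremental cost-effectiveness analysis.

Each patient is simulated twice — once allocated to the hypothetical drug
and once under usual care — against common random-number streams, so the
arms differ only through the treatment effect.  Analytic perspectives are a
post-processing of the stored trajectories: every scenario sums a subset of
the discounted utility/cost components accrued per arm, and the ICER is the
incremental cost divided by the incremental QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .cohort import PatientBaseline
from .costs import CostBreakdown, CostTable, DrugPricing, one_time_charge
from .errors import ConfigurationError
from .hazards import (
    InstitutionalizationParams,
    MortalityParams,
    institutionalization_probability,
    mortality_probability,
)
from .progression import (
    Location,
    PatientState,
    ProgressionParams,
    Stage,
    apply_stopping_rule,
    assign_severity,
    cycle_discontinuation_probability,
    step_progression,
)
from .utility import UtilityModel

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = [
    "ScenarioSpec",
    "builtin_scenarios",
    "Trajectory",
    "TrajectoryPair",
    "ArmAccount",
    "PairAccount",
    "CEAResult",
    "OneTimeResult",
    "SuiteResult",
    "simulate_patient_pair",
    "simulate_cohort_pairs",
    "account_trajectory",
    "account_pair",
    "evaluate_scenario",
    "compose_scenario",
    "run_scenario_suite",
]


class ScenarioSpec(BaseModel):
    """Which utility and cost components a perspective includes."""

    model_config = ConfigDict(extra="forbid")

    id: str
    include_caregiver_utility: bool = False
    include_patient_healthcare: bool = True
    include_caregiver_healthcare: bool = False
    include_patient_nonhealthcare: bool = False
    include_caregiver_productivity: bool = False
    discount_rate: float = Field(default=0.03, ge=0)

    def included_cost_components(self) -> tuple[str, ...]:
        comps = ["drug"]
        if self.include_patient_healthcare:
            comps.append("patient_healthcare")
        if self.include_patient_nonhealthcare:
            comps.append("patient_nonhealthcare")
        if self.include_caregiver_healthcare:
            comps.append("caregiver_healthcare")
        if self.include_caregiver_productivity:
            comps.append("caregiver_productivity")
        return tuple(comps)


def builtin_scenarios(discount_rate: float = 0.03) -> list[ScenarioSpec]:
    """The six standard perspectives A-F.

    A: patient utility + patient health care (and drug) costs only.
    B: A + caregiver health care costs.
    C: B + caregiver utility.
    D: A + patient non-health-care costs.
    E: B + patient non-health-care + caregiver productivity costs.
    F: everything.
    """
    kw = dict(discount_rate=discount_rate)
    return [
        ScenarioSpec(id="A", **kw),
        ScenarioSpec(id="B", include_caregiver_healthcare=True, **kw),
        ScenarioSpec(id="C", include_caregiver_healthcare=True, include_caregiver_utility=True, **kw),
        ScenarioSpec(id="D", include_patient_nonhealthcare=True, **kw),
        ScenarioSpec(
            id="E",
            include_caregiver_healthcare=True,
            include_patient_nonhealthcare=True,
            include_caregiver_productivity=True,
            **kw,
        ),
        ScenarioSpec(
            id="F",
            include_caregiver_utility=True,
            include_caregiver_healthcare=True,
            include_patient_nonhealthcare=True,
            include_caregiver_productivity=True,
            **kw,
        ),
    ]


@dataclass(slots=True)
class Trajectory:
    """Per-cycle record of one arm of one patient (state at cycle start)."""

    mmse: np.ndarray
    cdrsb: np.ndarray
    npi: np.ndarray
    stage: np.ndarray  # int8 codes per Stage
    residential: np.ndarray  # bool
    on_treatment: np.ndarray  # bool
    n_cycles: int
    horizon_cycles: int
    died: bool


@dataclass(slots=True)
class TrajectoryPair:
    baseline: PatientBaseline
    treated: Trajectory
    untreated: Trajectory


@dataclass(slots=True)
class ParamsBundle:
    """Everything the simulator needs besides the cohort."""

    progression: ProgressionParams
    mortality: MortalityParams
    institutionalization: InstitutionalizationParams
    max_age: float = 105.0


def _initial_state(baseline: PatientBaseline, params: ProgressionParams, treated: bool) -> PatientState:
    converted = baseline.cdrsb0 >= params.conversion_cdrsb_threshold
    state = PatientState(
        cycle=0,
        age=baseline.age,
        mmse=float(baseline.mmse0),
        cdrsb=baseline.cdrsb0,
        npi=baseline.npi0,
        stage=assign_severity(float(baseline.mmse0), converted),
        location=Location.COMMUNITY,
        alive=True,
        on_treatment=treated,
        months_in_stage=0.0,
        converted=converted,
        has_caregiver=baseline.has_caregiver,
    )
    return apply_stopping_rule(state, params)


def _run_arm(
    baseline: PatientBaseline,
    bundle: ParamsBundle,
    draws_disc: np.ndarray,
    draws_inst: np.ndarray,
    draws_mort: np.ndarray,
    treated: bool,
) -> Trajectory:
    prog = bundle.progression
    cl = prog.cycle_length_months
    horizon = draws_disc.shape[0]
    trailing = max(1, round(12.0 / cl))  # cycles per year for the decline rate

    state = _initial_state(baseline, prog, treated)
    mmse_hist = [state.mmse]
    rec_mmse: list[float] = []
    rec_cdrsb: list[float] = []
    rec_npi: list[float] = []
    rec_stage: list[int] = []
    rec_res: list[bool] = []
    rec_tx: list[bool] = []
    died = False

    for t in range(horizon):
        rec_mmse.append(state.mmse)
        rec_cdrsb.append(state.cdrsb)
        rec_npi.append(state.npi)
        rec_stage.append(int(state.stage))
        rec_res.append(state.location is Location.RESIDENTIAL)
        rec_tx.append(state.on_treatment)

        new = step_progression(state, prog, state.on_treatment)
        mmse_hist.append(new.mmse)
        if len(mmse_hist) > trailing:
            new.annual_mmse_decline = mmse_hist[-trailing - 1] - new.mmse
        apply_stopping_rule(new, prog)
        if new.on_treatment and draws_disc[t] < cycle_discontinuation_probability(prog):
            new.on_treatment = False
        if new.location is Location.COMMUNITY:
            p_inst = institutionalization_probability(
                new, baseline, bundle.institutionalization, cl
            )
            if draws_inst[t] < p_inst:
                new.location = Location.RESIDENTIAL
        p_mort = mortality_probability(new, baseline, bundle.mortality, cl)
        if draws_mort[t] < p_mort:
            new.alive = False
        state = new
        if not state.alive:
            died = True
            break

    return Trajectory(
        mmse=np.asarray(rec_mmse),
        cdrsb=np.asarray(rec_cdrsb),
        npi=np.asarray(rec_npi),
        stage=np.asarray(rec_stage, dtype=np.int8),
        residential=np.asarray(rec_res, dtype=bool),
        on_treatment=np.asarray(rec_tx, dtype=bool),
        n_cycles=len(rec_mmse),
        horizon_cycles=horizon,
        died=died,
    )


def simulate_patient_pair(
    baseline: PatientBaseline,
    bundle: ParamsBundle,
    seed: int,
    common_random_numbers: bool = True,
) -> TrajectoryPair:
    """Simulate one patient under drug and under usual care.

    With ``common_random_numbers`` both arms index identical uniform streams
    (one per event type, positionally by cycle), so a null treatment effect
    yields byte-identical trajectories; otherwise each arm gets independent
    streams (used only to demonstrate the variance penalty).
    """
    prog = bundle.progression
    horizon = max(1, math.ceil((bundle.max_age - baseline.age) * 12.0 / prog.cycle_length_months))
    ss = np.random.SeedSequence(entropy=(seed, baseline.id))
    n_streams = 3 if common_random_numbers else 6
    children = ss.spawn(n_streams)
    draws = [np.random.default_rng(c).random(horizon) for c in children]
    treated = _run_arm(baseline, bundle, draws[0], draws[1], draws[2], treated=True)
    d = draws[:3] if common_random_numbers else draws[3:]
    untreated = _run_arm(baseline, bundle, d[0], d[1], d[2], treated=False)
    return TrajectoryPair(baseline=baseline, treated=treated, untreated=untreated)


def simulate_cohort_pairs(
    cohort: Sequence[PatientBaseline],
    bundle: ParamsBundle,
    seed: int,
    common_random_numbers: bool = True,
) -> list[TrajectoryPair]:
    return [
        simulate_patient_pair(b, bundle, seed, common_random_numbers=common_random_numbers)
        for b in cohort
    ]


@dataclass(slots=True)
class ArmAccount:
    """Discounted per-patient totals for one arm (all components, pre-perspective)."""

    qalys_patient: float
    qalys_caregiver: float
    life_years: float
    costs: CostBreakdown


@dataclass(slots=True)
class PairAccount:
    treated: ArmAccount
    untreated: ArmAccount


def account_trajectory(
    traj: Trajectory,
    baseline: PatientBaseline,
    utility_model: UtilityModel,
    cost_table: CostTable,
    pricing: DrugPricing,
    discount_rate: float,
    cycle_length_months: float = 1.0,
    treated_arm: bool = False,
) -> ArmAccount:
    """Discount and accumulate every utility/cost component for one trajectory."""
    if discount_rate < 0:
        raise ConfigurationError(f"discount_rate must be >= 0, got {discount_rate}")
    frac = cycle_length_months / 12.0
    n = traj.n_cycles
    horizon = traj.horizon_cycles
    disc_all = (1.0 + discount_rate) ** (-np.arange(horizon) * frac)
    disc = disc_all[:n]

    m = utility_model
    u = (
        m.intercept
        + m.coef_mmse * traj.mmse
        + m.coef_npi * traj.npi
        + np.where(
            traj.residential,
            m.coef_institutionalized,
            m.coef_lives_with_caregiver if baseline.has_caregiver else 0.0,
        )
    )
    u = np.clip(u, 0.0, 1.0)
    qalys_patient = float((u * disc).sum() * frac)
    life_years = float(disc.sum() * frac)

    qalys_caregiver = 0.0
    if baseline.has_caregiver:
        cg_age = baseline.caregiver_age + np.arange(horizon) * frac
        lowers = np.array([lo for lo, _ in m.population_norm_by_age])
        values = np.array([v for _, v in m.population_norm_by_age])
        norm = values[np.clip(np.searchsorted(lowers, cg_age, side="right") - 1, 0, None)]
        w = norm.copy()  # default: patient dead (tail) or institutionalized
        alive = np.zeros(horizon, dtype=bool)
        alive[:n] = True
        community = alive.copy()
        community[:n] &= ~traj.residential
        mci = np.zeros(horizon, dtype=bool)
        mci[:n] = traj.stage == int(Stage.MCI)
        band = np.zeros(horizon)
        band[:n] = np.where(
            traj.mmse >= 21.0,
            m.caregiver_dementia_utility.mmse_21_plus,
            np.where(
                traj.mmse >= 15.0,
                m.caregiver_dementia_utility.mmse_15_20,
                m.caregiver_dementia_utility.mmse_0_14,
            ),
        )
        w = np.where(community & mci, m.caregiver_mci_utility, np.where(community, band, w))
        qalys_caregiver = float((w * disc_all).sum() * frac)

    stage_idx = traj.stage
    caregiver_on = (
        (~traj.residential) if baseline.has_caregiver else np.zeros(n, dtype=bool)
    )
    cl = cycle_length_months

    def stage_cost(vals) -> float:
        return float((np.asarray(vals.as_tuple())[stage_idx] * cl * disc).sum())

    def stage_cost_cg(vals) -> float:
        arr = np.asarray(vals.as_tuple())[stage_idx] * cl
        return float((arr * caregiver_on * disc).sum())

    drug = 0.0
    if treated_arm:
        if pricing.mode == "repeated":
            drug = float(
                (traj.on_treatment * (pricing.annual_price / 12.0 * cl) * disc).sum()
            )
        else:
            drug = one_time_charge(pricing)  # charged at t=0, discount factor 1
    costs = CostBreakdown(
        drug=drug,
        patient_healthcare=stage_cost(cost_table.patient_healthcare),
        patient_nonhealthcare=stage_cost(cost_table.patient_nonhealthcare),
        caregiver_healthcare=stage_cost_cg(cost_table.caregiver_healthcare),
        caregiver_productivity=stage_cost_cg(cost_table.caregiver_productivity),
    )
    return ArmAccount(
        qalys_patient=qalys_patient,
        qalys_caregiver=qalys_caregiver,
        life_years=life_years,
        costs=costs,
    )


def account_pair(
    pair: TrajectoryPair,
    utility_model: UtilityModel,
    cost_table: CostTable,
    pricing: DrugPricing,
    discount_rate: float,
    cycle_length_months: float = 1.0,
) -> PairAccount:
    kw = dict(
        utility_model=utility_model,
        cost_table=cost_table,
        pricing=pricing,
        discount_rate=discount_rate,
        cycle_length_months=cycle_length_months,
    )
    return PairAccount(
        treated=account_trajectory(pair.treated, pair.baseline, treated_arm=True, **kw),
        untreated=account_trajectory(pair.untreated, pair.baseline, treated_arm=False, **kw),
    )


@dataclass(slots=True)
class ArmSummary:
    """Cohort means for one arm under one scenario."""

    qalys_patient: float
    qalys_caregiver: float
    qalys_total: float
    life_years: float
    costs: CostBreakdown
    cost_total: float


@dataclass(slots=True)
class CEAResult:
    scenario_id: str
    n: int
    treated: ArmSummary
    untreated: ArmSummary
    incremental_cost: float
    incremental_qalys: float
    incremental_life_years: float
    icer: float | None
    status: str  # "ok" | "dominant" | "dominated" | "undefined"
    se_incremental_cost: float
    se_incremental_qalys: float
    included_cost_components: tuple[str, ...] = ()
    seed: int | None = None

    @property
    def icer_sort_key(self) -> float:
        """Orderable ICER: dominant sorts below every finite value, dominated above."""
        if self.status == "dominant":
            return -math.inf
        if self.status in ("dominated", "undefined"):
            return math.inf
        return self.icer  # type: ignore[return-value]


def _classify(inc_cost: float, inc_qalys: float) -> tuple[float | None, str]:
    if inc_qalys > 0 and inc_cost >= 0:
        return inc_cost / inc_qalys, "ok"
    if inc_qalys > 0 and inc_cost < 0:
        return inc_cost / inc_qalys, "dominant"
    if inc_qalys < 0 and inc_cost > 0:
        return None, "dominated"
    if inc_qalys == 0:
        return None, "undefined"
    return inc_cost / inc_qalys, "ok"


def compose_scenario(
    accounts: Sequence[PairAccount],
    scenario: ScenarioSpec,
    seed: int | None = None,
) -> CEAResult:
    """Sum a scenario's included components over precomputed pair accounts."""
    if not accounts:
        raise ConfigurationError("compose_scenario requires at least one pair account")
    comps = scenario.included_cost_components()
    n = len(accounts)

    def arm_summary(get) -> ArmSummary:
        qp = np.array([get(a).qalys_patient for a in accounts])
        qc = np.array([get(a).qalys_caregiver for a in accounts])
        ly = np.array([get(a).life_years for a in accounts])
        cb = CostBreakdown(
            **{
                c: float(np.mean([getattr(get(a).costs, c) for a in accounts]))
                for c in comps
            }
        )
        qtot = qp.mean() + (qc.mean() if scenario.include_caregiver_utility else 0.0)
        return ArmSummary(
            qalys_patient=float(qp.mean()),
            qalys_caregiver=float(qc.mean()),
            qalys_total=float(qtot),
            life_years=float(ly.mean()),
            costs=cb,
            cost_total=cb.total,
        )

    treated = arm_summary(lambda a: a.treated)
    untreated = arm_summary(lambda a: a.untreated)

    def inc_qaly(a: PairAccount) -> float:
        dq = a.treated.qalys_patient - a.untreated.qalys_patient
        if scenario.include_caregiver_utility:
            dq += a.treated.qalys_caregiver - a.untreated.qalys_caregiver
        return dq

    def inc_cost(a: PairAccount) -> float:
        return sum(
            getattr(a.treated.costs, c) - getattr(a.untreated.costs, c) for c in comps
        )

    dq = np.array([inc_qaly(a) for a in accounts])
    dc = np.array([inc_cost(a) for a in accounts])
    inc_qalys = float(dq.mean())
    inc_cost_mean = float(dc.mean())
    icer, status = _classify(inc_cost_mean, inc_qalys)
    return CEAResult(
        scenario_id=scenario.id,
        n=n,
        treated=treated,
        untreated=untreated,
        incremental_cost=inc_cost_mean,
        incremental_qalys=inc_qalys,
        incremental_life_years=float(
            np.mean([a.treated.life_years - a.untreated.life_years for a in accounts])
        ),
        icer=icer,
        status=status,
        se_incremental_cost=float(dc.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        se_incremental_qalys=float(dq.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        included_cost_components=comps,
        seed=seed,
    )


def evaluate_scenario(
    pairs: Sequence[TrajectoryPair],
    scenario: ScenarioSpec,
    utility_model: UtilityModel,
    cost_table: CostTable,
    pricing: DrugPricing,
    cycle_length_months: float = 1.0,
    seed: int | None = None,
) -> CEAResult:
    """Account the trajectory pairs under the scenario's discount rate and compose."""
    if not pairs:
        raise ConfigurationError("evaluate_scenario requires at least one trajectory pair")
    accounts = [
        account_pair(
            p, utility_model, cost_table, pricing, scenario.discount_rate, cycle_length_months
        )
        for p in pairs
    ]
    return compose_scenario(accounts, scenario, seed=seed)


@dataclass(slots=True)
class OneTimeResult:
    label: str
    mode: str
    effect_scale: float
    price: float
    result: CEAResult


@dataclass(slots=True)
class SuiteResult:
    scenario_results: list[CEAResult]
    onetime_results: list[OneTimeResult]
    seed: int
    n: int
    config_hash: str = ""


def run_scenario_suite(config: "RunConfig") -> SuiteResult:
    """Full analysis: simulate once, evaluate perspectives A-F and the one-time sweep.

    All perspectives are composed from the same trajectory pairs; the
    one-time sweep re-simulates only when the effect scale changes (the
    price is pure post-processing).
    """
    from .config import config_hash  # local import to avoid a cycle
    from .cohort import generate_cohort

    cohort_cfg = config.cohort.model_copy(update={"n": config.n, "seed": config.seed})
    cohort = generate_cohort(cohort_cfg)
    bundle = ParamsBundle(
        progression=config.progression,
        mortality=config.mortality,
        institutionalization=config.institutionalization,
        max_age=config.max_age,
    )
    cl = config.progression.cycle_length_months
    pairs = simulate_cohort_pairs(cohort, bundle, config.seed)

    scenario_results: list[CEAResult] = []
    by_rate: dict[float, list[PairAccount]] = {}
    for sc in config.scenarios:
        if sc.discount_rate not in by_rate:
            by_rate[sc.discount_rate] = [
                account_pair(p, config.utilities, config.costs, config.pricing, sc.discount_rate, cl)
                for p in pairs
            ]
        scenario_results.append(
            compose_scenario(by_rate[sc.discount_rate], sc, seed=config.seed)
        )

    base_rate = config.scenarios[0].discount_rate if config.scenarios else 0.03
    base_scenario = ScenarioSpec(id="A", discount_rate=base_rate)
    onetime: list[OneTimeResult] = []
    base = next((r for r in scenario_results if r.scenario_id == "A"), None)
    if base is None:
        base = compose_scenario(
            by_rate.get(base_rate)
            or [
                account_pair(p, config.utilities, config.costs, config.pricing, base_rate, cl)
                for p in pairs
            ],
            base_scenario,
            seed=config.seed,
        )
    onetime.append(
        OneTimeResult(
            label="base case (repeated)",
            mode="repeated",
            effect_scale=1.0,
            price=config.pricing.annual_price,
            result=base,
        )
    )
    base_effect = config.progression.treatment_effect
    for scale in config.onetime_effect_scales:
        effect = min(1.0, base_effect * scale)
        if scale == 1.0:
            scaled_pairs = pairs
        else:
            prog = config.progression.model_copy(update={"treatment_effect": effect})
            scaled_pairs = simulate_cohort_pairs(
                cohort,
                ParamsBundle(
                    progression=prog,
                    mortality=config.mortality,
                    institutionalization=config.institutionalization,
                    max_age=config.max_age,
                ),
                config.seed,
            )
        for price in config.onetime_prices:
            pricing = DrugPricing(
                mode="one_time", annual_price=0.0, one_time_price=price, effect_scale=scale
            )
            res = evaluate_scenario(
                scaled_pairs,
                base_scenario.model_copy(update={"id": f"one_time[{scale:g}x,{price:g}]"}),
                config.utilities,
                config.costs,
                pricing,
                cl,
                seed=config.seed,
            )
            onetime.append(
                OneTimeResult(
                    label=f"one-time, effect x{scale:g}, ${price:,.0f}",
                    mode="one_time",
                    effect_scale=scale,
                    price=price,
                    result=res,
                )
            )

    return SuiteResult(
        scenario_results=scenario_results,
        onetime_results=onetime,
        seed=config.seed,
        n=config.n,
        config_hash=config_hash(config),
    )
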