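import pytest

from adcea import (
    CohortConfig,
    CostTable,
    DrugPricing,
    InstitutionalizationParams,
    Location,
    MortalityParams,
    ParamsBundle,
    PatientBaseline,
    PatientState,
    ProgressionParams,
    Stage,
    UtilityModel,
    default_config,
    generate_cohort,
)


@pytest.fixture
def progression_params() -> ProgressionParams:
    return ProgressionParams()


@pytest.fixture
def utility_model() -> UtilityModel:
    return UtilityModel()


@pytest.fixture
def cost_table() -> CostTable:
    return CostTable()


@pytest.fixture
def pricing() -> DrugPricing:
    return DrugPricing()


@pytest.fixture
def baseline() -> PatientBaseline:
    return PatientBaseline(
        id=0,
        age=73.0,
        sex="female",
        mmse0=27,
        cdrsb0=1.5,
        npi0=3.0,
        has_caregiver=True,
        caregiver_age=70.0,
    )


@pytest.fixture
def bundle() -> ParamsBundle:
    cfg = default_config()
    return ParamsBundle(
        progression=cfg.progression,
        mortality=cfg.mortality,
        institutionalization=cfg.institutionalization,
        max_age=cfg.max_age,
    )


@pytest.fixture
def small_cohort() -> list[PatientBaseline]:
    return generate_cohort(CohortConfig(n=20, seed=7))


def make_state(
    mmse: float = 27.0,
    cdrsb: float = 1.5,
    npi: float = 3.0,
    stage: Stage = Stage.MCI,
    location: Location = Location.COMMUNITY,
    alive: bool = True,
    on_treatment: bool = False,
    months_in_stage: float = 0.0,
    converted: bool = False,
    has_caregiver: bool = True,
    age: float = 73.0,
    cycle: int = 0,
    annual_mmse_decline: float = 0.0,
) -> PatientState:
    return PatientState(
        cycle=cycle,
        age=age,
        mmse=mmse,
        cdrsb=cdrsb,
        npi=npi,
        stage=stage,
        location=location,
        alive=alive,
        on_treatment=on_treatment,
        months_in_stage=months_in_stage,
        converted=converted,
        has_caregiver=has_caregiver,
        annual_mmse_decline=annual_mmse_decline,
    )


@pytest.fixture
def state_factory():
    return make_state
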