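"""Independent cohort-level expectation-propagation oracle.

Computes, for a single baseline patient, the exact expected discounted
QALYs, life-years and cost components of each arm under the same per-cycle
event ordering as the microsimulation engine — but analytically: the
cognitive trajectory is deterministic conditional on the cycle at which
drug exposure ends, so the oracle enumerates discontinuation branches
(geometric weights, truncated by the severity stopping rule) and, within
each branch, propagates the probability mass over
{alive-community, alive-residential, dead} using the per-cycle mortality
and institutionalization probabilities recomputed here from first
principles.  No package simulation or accounting code is called.
"""

from __future__ import annotations

import bisect
import math
from importlib import resources

import pandas as pd

MCI, MILD, MODERATE, SEVERE = 0, 1, 2, 3


def _load_life_table() -> dict[str, list[tuple[float, float]]]:
    with resources.as_file(resources.files("adcea.data") / "life_table.csv") as p:
        df = pd.read_csv(p)
    out: dict[str, list[tuple[float, float]]] = {"female": [], "male": []}
    for row in df.itertuples(index=False):
        out[str(row.sex)].append((float(row.age_lower), float(row.annual_q)))
    for sex in out:
        out[sex].sort()
    return out


def _annual_q(table, age: float, sex: str) -> float:
    rows = table[sex]
    lowers = [lo for lo, _ in rows]
    i = max(bisect.bisect_right(lowers, age) - 1, 0)
    return rows[i][1]


def _stage_of(mmse: float, converted: bool) -> int:
    if not converted:
        return MCI
    if mmse >= 21.0:
        return MILD
    if mmse >= 15.0:
        return MODERATE
    return SEVERE


def _cognitive_path(baseline: dict, prog: dict, on_last_cycle: int, horizon: int):
    """Deterministic per-cycle path with treatment on for progression cycles
    0..on_last_cycle inclusive (on_last_cycle=-1 means never treated)."""
    cdrsb_rates = prog["cdrsb_rates"]  # tuple by stage, points/year
    npi_rates = prog["npi_rates"]
    coupling = prog["mmse_per_cdrsb"]
    effect = prog["treatment_effect"]
    threshold = prog["conversion_threshold"]

    mmse = float(baseline["mmse0"])
    cdrsb = baseline["cdrsb0"]
    npi = baseline["npi0"]
    converted = cdrsb >= threshold
    stage = _stage_of(mmse, converted)
    months = 0.0
    mmse_series = [mmse]

    start = []  # (mmse, npi, stage) at cycle start
    post = []  # (mmse, stage, months, decline) after the cycle's progression
    for t in range(horizon):
        start.append((mmse, npi, stage))
        on = t <= on_last_cycle
        inc = cdrsb_rates[stage] / 12.0 * ((1.0 - effect) if on else 1.0)
        cdrsb = min(18.0, max(0.0, cdrsb + inc))
        new_mmse = min(30.0, max(0.0, mmse - coupling * inc))
        npi = max(0.0, npi + npi_rates[stage] / 12.0)
        converted = converted or cdrsb >= threshold
        new_stage = _stage_of(new_mmse, converted)
        months = months + 1.0 if new_stage == stage else 0.0
        mmse_series.append(new_mmse)
        decline = mmse_series[-13] - new_mmse if len(mmse_series) > 12 else 0.0
        post.append((new_mmse, new_stage, months, decline))
        mmse, stage = new_mmse, new_stage
    return start, post


def _stop_cycle(baseline: dict, prog: dict, horizon: int, stop_stage: int) -> int:
    """First cycle whose post-progression stage reaches the stopping stage,
    under uninterrupted treatment."""
    _, post = _cognitive_path(baseline, prog, on_last_cycle=horizon, horizon=horizon)
    for t, (_, stage, _, _) in enumerate(post):
        if stage >= stop_stage:
            return t
    return horizon


def _branch_outcomes(
    baseline: dict,
    params: dict,
    on_last_cycle: int,
    treated_arm: bool,
    horizon: int,
    discount_rate: float,
):
    table = params["life_table"]
    mort = params["mortality"]
    inst = params["institutionalization"]
    util = params["utility"]
    cost = params["costs"]
    sex = baseline["sex"]
    female = sex == "female"
    age0 = baseline["age"]
    cg_age0 = baseline["caregiver_age"]

    start, post = _cognitive_path(baseline, params["progression"], on_last_cycle, horizon)

    a_c, a_r = 1.0, 0.0
    out = {
        "qalys_patient": 0.0,
        "qalys_caregiver": 0.0,
        "life_years": 0.0,
        "drug": 0.0,
        "patient_healthcare": 0.0,
        "patient_nonhealthcare": 0.0,
        "caregiver_healthcare": 0.0,
        "caregiver_productivity": 0.0,
    }
    bands = util["caregiver_bands"]  # (u_21_plus, u_15_20, u_0_14)
    norms = util["population_norms"]  # sorted (age_lower, utility)
    norm_lowers = [lo for lo, _ in norms]

    def norm_at(age: float) -> float:
        return norms[max(bisect.bisect_right(norm_lowers, age) - 1, 0)][1]

    for t in range(horizon):
        mmse_t, npi_t, stage_t = start[t]
        disc = (1.0 + discount_rate) ** (-t / 12.0)
        alive = a_c + a_r

        u_base = util["intercept"] + util["coef_mmse"] * mmse_t + util["coef_npi"] * npi_t
        u_comm = min(1.0, max(0.0, u_base + util["coef_caregiver"]))
        u_res = min(1.0, max(0.0, u_base + util["coef_institutionalized"]))
        out["qalys_patient"] += (a_c * u_comm + a_r * u_res) * disc / 12.0
        out["life_years"] += alive * disc / 12.0

        if stage_t == MCI:
            w_comm = 1.0
        elif mmse_t >= 21.0:
            w_comm = bands[0]
        elif mmse_t >= 15.0:
            w_comm = bands[1]
        else:
            w_comm = bands[2]
        w_norm = norm_at(cg_age0 + t / 12.0)
        out["qalys_caregiver"] += (a_c * w_comm + (1.0 - a_c) * w_norm) * disc / 12.0

        out["patient_healthcare"] += alive * cost["patient_healthcare"][stage_t] * disc
        out["patient_nonhealthcare"] += alive * cost["patient_nonhealthcare"][stage_t] * disc
        out["caregiver_healthcare"] += a_c * cost["caregiver_healthcare"][stage_t] * disc
        out["caregiver_productivity"] += a_c * cost["caregiver_productivity"][stage_t] * disc
        if treated_arm and t <= on_last_cycle:
            out["drug"] += alive * cost["annual_drug_price"] / 12.0 * disc

        mmse_next, stage_next, months_next, decline = post[t]
        age_next = age0 + (t + 1) / 12.0
        q = _annual_q(table, age_next, sex)
        hr = math.exp(
            mort["beta_mmse"] * (30.0 - mmse_next)
            + mort["beta_decline"] * decline
            + mort["beta_baseline_mmse"] * (30.0 - baseline["mmse0"])
        )
        p_mort = min(1.0, max(0.0, 1.0 - (1.0 - q) ** (hr / 12.0)))
        rate = inst["base_rates"][stage_next] * math.exp(
            inst["gamma_time_in_stage"] * months_next
            + inst["gamma_age"] * (age_next - inst["reference_age"])
        )
        if female:
            rate *= inst["female_multiplier"]
        p_inst = min(1.0, max(0.0, rate))

        a_r = (a_r + a_c * p_inst) * (1.0 - p_mort)
        a_c = a_c * (1.0 - p_inst) * (1.0 - p_mort)
    return out


def expected_outcomes(
    baseline: dict, params: dict, treated_arm: bool, discount_rate: float
) -> dict[str, float]:
    """Expected discounted outcomes for one arm of one baseline patient."""
    horizon = max(1, math.ceil((params["max_age"] - baseline["age"]) * 12.0))
    if not treated_arm:
        return _branch_outcomes(baseline, params, -1, False, horizon, discount_rate)

    prog = params["progression"]
    p = 1.0 - (1.0 - prog["annual_discontinuation"]) ** (1.0 / 12.0)
    s_stop = _stop_cycle(baseline, prog, horizon, params["stop_stage"])

    total = None
    weight_sum = 0.0
    branches = [(d, (1.0 - p) ** d * p) for d in range(s_stop)]
    branches.append((s_stop, (1.0 - p) ** s_stop))
    for on_last, weight in branches:
        if weight == 0.0:
            continue
        res = _branch_outcomes(baseline, params, on_last, True, horizon, discount_rate)
        if total is None:
            total = {k: 0.0 for k in res}
        for k, v in res.items():
            total[k] += weight * v
        weight_sum += weight
    assert abs(weight_sum - 1.0) < 1e-12
    return total
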