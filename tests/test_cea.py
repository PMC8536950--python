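import numpy as np
import pytest

from adcea import (
    CostBreakdown,
    DrugPricing,
    Location,
    ParamsBundle,
    ScenarioSpec,
    Stage,
    accrue_costs,
    accrue_qalys,
    account_pair,
    account_trajectory,
    builtin_scenarios,
    caregiver_utility,
    compose_scenario,
    cycle_costs,
    evaluate_scenario,
    patient_utility,
    simulate_cohort_pairs,
    simulate_patient_pair,
)
from adcea.errors import ConfigurationError
from tests.conftest import make_state


def null_effect_bundle(bundle) -> ParamsBundle:
    prog = bundle.progression.model_copy(update={"treatment_effect": 0.0})
    return ParamsBundle(
        progression=prog,
        mortality=bundle.mortality,
        institutionalization=bundle.institutionalization,
        max_age=bundle.max_age,
    )


class TestSimulatePatientPair:
    def test_null_effect_identical_trajectories(self, baseline, bundle):
        pair = simulate_patient_pair(baseline, null_effect_bundle(bundle), seed=1)
        t, u = pair.treated, pair.untreated
        assert t.n_cycles == u.n_cycles
        np.testing.assert_array_equal(t.mmse, u.mmse)
        np.testing.assert_array_equal(t.cdrsb, u.cdrsb)
        np.testing.assert_array_equal(t.stage, u.stage)
        np.testing.assert_array_equal(t.residential, u.residential)

    def test_treated_dominates_on_cdrsb(self, baseline, bundle):
        pair = simulate_patient_pair(baseline, bundle, seed=2)
        n = min(pair.treated.n_cycles, pair.untreated.n_cycles)
        assert np.all(pair.treated.cdrsb[:n] <= pair.untreated.cdrsb[:n] + 1e-12)

    def test_determinism(self, baseline, bundle):
        a = simulate_patient_pair(baseline, bundle, seed=3)
        b = simulate_patient_pair(baseline, bundle, seed=3)
        assert a.treated.n_cycles == b.treated.n_cycles
        np.testing.assert_array_equal(a.treated.mmse, b.treated.mmse)
        np.testing.assert_array_equal(a.untreated.mmse, b.untreated.mmse)

    def test_different_seeds_differ(self, baseline, bundle):
        a = simulate_patient_pair(baseline, bundle, seed=1)
        b = simulate_patient_pair(baseline, bundle, seed=2)
        assert (
            a.untreated.n_cycles != b.untreated.n_cycles
            or not np.array_equal(a.untreated.residential, b.untreated.residential)
        )

    def test_untreated_never_on_treatment(self, baseline, bundle):
        pair = simulate_patient_pair(baseline, bundle, seed=4)
        assert not pair.untreated.on_treatment.any()

    def test_treatment_stops_at_moderate(self, baseline, bundle):
        pair = simulate_patient_pair(baseline, bundle, seed=5)
        on = pair.treated.on_treatment
        moderate_plus = pair.treated.stage >= int(Stage.MODERATE)
        assert not np.any(on & moderate_plus)

    def test_treatment_never_restarts(self, baseline, bundle):
        pair = simulate_patient_pair(baseline, bundle, seed=6)
        on = pair.treated.on_treatment.astype(int)
        assert all(b - a <= 0 for a, b in zip(on, on[1:]))


class TestAccountTrajectoryParity:
    """The vectorized accountant must equal cycle-by-cycle scalar-op accrual."""

    def _scalar_account(self, traj, baseline, um, ct, pricing, rate):
        ustream, cstream = [], []
        for t in range(traj.n_cycles):
            state = make_state(
                mmse=float(traj.mmse[t]),
                npi=float(traj.npi[t]),
                stage=Stage(int(traj.stage[t])),
                converted=traj.stage[t] > 0,
                location=Location.RESIDENTIAL if traj.residential[t] else Location.COMMUNITY,
                on_treatment=bool(traj.on_treatment[t]),
                has_caregiver=baseline.has_caregiver,
            )
            ustream.append((t, patient_utility(state, um)))
            cstream.append((t, cycle_costs(state, ct, pricing)))
        qalys = accrue_qalys(ustream, rate)
        costs = accrue_costs(cstream, rate)
        cg_stream = []
        for t in range(traj.horizon_cycles):
            if t < traj.n_cycles:
                state = make_state(
                    mmse=float(traj.mmse[t]),
                    npi=float(traj.npi[t]),
                    stage=Stage(int(traj.stage[t])),
                    converted=traj.stage[t] > 0,
                    location=Location.RESIDENTIAL if traj.residential[t] else Location.COMMUNITY,
                    has_caregiver=True,
                )
            else:
                state = make_state(alive=False)
            cg_stream.append((t, caregiver_utility(state, baseline.caregiver_age + t / 12.0, um)))
        cg_qalys = accrue_qalys(cg_stream, rate)
        return qalys, cg_qalys, costs

    def test_parity_with_scalar_ops(self, baseline, bundle, utility_model, cost_table, pricing):
        pair = simulate_patient_pair(baseline, bundle, seed=11)
        for traj, treated_arm in ((pair.treated, True), (pair.untreated, False)):
            acc = account_trajectory(
                traj, baseline, utility_model, cost_table, pricing, 0.03, treated_arm=treated_arm
            )
            qalys, cg_qalys, costs = self._scalar_account(
                traj, baseline, utility_model, cost_table, pricing, 0.03
            )
            assert acc.qalys_patient == pytest.approx(qalys, rel=1e-10)
            assert acc.qalys_caregiver == pytest.approx(cg_qalys, rel=1e-10)
            for comp in ("patient_healthcare", "patient_nonhealthcare",
                         "caregiver_healthcare", "caregiver_productivity"):
                assert getattr(acc.costs, comp) == pytest.approx(getattr(costs, comp), rel=1e-10)
            if treated_arm:
                assert acc.costs.drug == pytest.approx(costs.drug, rel=1e-10)
            else:
                assert acc.costs.drug == 0.0


class TestScenarios:
    def test_builtin_matrix(self):
        by_id = {s.id: s for s in builtin_scenarios()}
        assert set(by_id) == set("ABCDEF")
        assert all(s.include_patient_healthcare for s in by_id.values())
        assert [by_id[i].include_caregiver_utility for i in "ABCDEF"] == [
            False, False, True, False, False, True]
        assert [by_id[i].include_caregiver_healthcare for i in "ABCDEF"] == [
            False, True, True, False, True, True]
        assert [by_id[i].include_patient_nonhealthcare for i in "ABCDEF"] == [
            False, False, False, True, True, True]
        assert [by_id[i].include_caregiver_productivity for i in "ABCDEF"] == [
            False, False, False, False, True, True]

    def test_qalys_differ_only_where_caregiver_utility_included(self, small_cohort, bundle,
                                                                utility_model, cost_table, pricing):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=8)
        results = {
            s.id: evaluate_scenario(pairs, s, utility_model, cost_table, pricing)
            for s in builtin_scenarios()
        }
        base = results["A"]
        for sid, r in results.items():
            assert r.treated.qalys_patient == pytest.approx(base.treated.qalys_patient)
            if sid in ("C", "F"):
                assert r.incremental_qalys != pytest.approx(base.incremental_qalys)
            else:
                assert r.incremental_qalys == pytest.approx(base.incremental_qalys)

    def test_comparator_drug_cost_zero(self, small_cohort, bundle, utility_model,
                                       cost_table, pricing):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=9)
        r = evaluate_scenario(pairs, builtin_scenarios()[0], utility_model, cost_table, pricing)
        assert r.untreated.costs.drug == 0.0
        assert r.treated.costs.drug > 0.0

    def test_post_processing_reproducible(self, small_cohort, bundle, utility_model,
                                          cost_table, pricing):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=10)
        sc = builtin_scenarios()[2]
        r1 = evaluate_scenario(pairs, sc, utility_model, cost_table, pricing)
        r2 = evaluate_scenario(pairs, sc, utility_model, cost_table, pricing)
        assert r1 == r2

    def test_zero_price_positive_effect_dominant(self, small_cohort, bundle, utility_model,
                                                 cost_table):
        free = DrugPricing(annual_price=0.0)
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=12)
        r = evaluate_scenario(
            pairs, ScenarioSpec(id="F", include_caregiver_utility=True,
                                include_caregiver_healthcare=True,
                                include_patient_nonhealthcare=True,
                                include_caregiver_productivity=True),
            utility_model, cost_table, free,
        )
        assert r.status == "dominant"
        assert r.incremental_cost < 0
        assert r.incremental_qalys > 0

    def test_caregiver_productivity_inclusion_lowers_icer(self, small_cohort, bundle,
                                                          utility_model, cost_table, pricing):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=13)
        without = ScenarioSpec(id="B", include_caregiver_healthcare=True)
        with_prod = ScenarioSpec(id="B+prod", include_caregiver_healthcare=True,
                                 include_caregiver_productivity=True)
        r_without = evaluate_scenario(pairs, without, utility_model, cost_table, pricing)
        r_with = evaluate_scenario(pairs, with_prod, utility_model, cost_table, pricing)
        assert r_with.incremental_cost <= r_without.incremental_cost
        assert r_with.icer_sort_key <= r_without.icer_sort_key

    def test_empty_pairs_rejected(self, utility_model, cost_table, pricing):
        with pytest.raises(ConfigurationError):
            evaluate_scenario([], builtin_scenarios()[0], utility_model, cost_table, pricing)


class TestOneTimePricing:
    def test_one_time_and_repeated_differ_only_in_drug(self, small_cohort, bundle,
                                                       utility_model, cost_table):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=14)
        repeated = DrugPricing(mode="repeated")
        onetime = DrugPricing(mode="one_time", annual_price=0.0, one_time_price=50_000)
        for pair in pairs[:5]:
            a_rep = account_pair(pair, utility_model, cost_table, repeated, 0.03)
            a_one = account_pair(pair, utility_model, cost_table, onetime, 0.03)
            assert a_one.treated.costs.drug == 50_000.0
            assert a_one.untreated.costs.drug == 0.0
            for comp in ("patient_healthcare", "patient_nonhealthcare",
                         "caregiver_healthcare", "caregiver_productivity"):
                assert getattr(a_rep.treated.costs, comp) == getattr(a_one.treated.costs, comp)
            assert a_rep.treated.qalys_patient == a_one.treated.qalys_patient

    def test_higher_price_higher_icer(self, small_cohort, bundle, utility_model, cost_table):
        pairs = simulate_cohort_pairs(small_cohort, bundle, seed=15)
        sc = builtin_scenarios()[0]
        icers = []
        for price in (50_000, 150_000):
            pricing = DrugPricing(mode="one_time", annual_price=0.0, one_time_price=price)
            icers.append(
                evaluate_scenario(pairs, sc, utility_model, cost_table, pricing).icer
            )
        assert icers[1] > icers[0]


class TestCaregiverAccrual:
    def test_norms_of_one_are_maximal(self, baseline, bundle, cost_table, pricing):
        from adcea import UtilityModel

        pair = simulate_patient_pair(baseline, bundle, seed=31)
        default_model = UtilityModel()
        max_model = UtilityModel(population_norm_by_age=((0.0, 1.0),))
        low_model = UtilityModel(population_norm_by_age=((0.0, 0.5),))
        accs = {
            name: account_trajectory(
                pair.untreated, baseline, model, cost_table, pricing, 0.03
            ).qalys_caregiver
            for name, model in (
                ("default", default_model), ("max", max_model), ("low", low_model)
            )
        }
        assert accs["max"] >= accs["default"] >= accs["low"]
        # with norms == 1 every cycle is bounded by the MCI utility, so the
        # total equals the horizon annuity only if the band values were 1 too
        assert accs["max"] <= pair.untreated.horizon_cycles / 12.0

    def test_accrual_switches_at_institutionalization_cycle(self, cost_table, pricing):
        import numpy as np

        from adcea import PatientBaseline, Trajectory, UtilityModel, account_trajectory

        model = UtilityModel(population_norm_by_age=((0.0, 0.6),))
        b = PatientBaseline(id=0, age=73.0, sex="female", mmse0=27, cdrsb0=1.0,
                            npi0=0.0, has_caregiver=True, caregiver_age=70.0)
        n, switch = 24, 10
        traj = Trajectory(
            mmse=np.full(n, 27.0),
            cdrsb=np.full(n, 1.0),
            npi=np.zeros(n),
            stage=np.zeros(n, dtype=np.int8),  # MCI throughout
            residential=np.arange(n) >= switch,
            on_treatment=np.zeros(n, dtype=bool),
            n_cycles=n,
            horizon_cycles=n,
            died=False,
        )
        acc = account_trajectory(traj, b, model, cost_table, pricing, 0.0)
        # 10 community cycles at 1.00, 14 residential cycles at the 0.6 norm
        assert acc.qalys_caregiver == pytest.approx((switch * 1.0 + (n - switch) * 0.6) / 12.0)


class TestCommonRandomNumbers:
    def test_crn_reduces_variance_of_incremental_qalys(self, bundle, utility_model,
                                                       cost_table, pricing):
        from adcea import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n=300, seed=21))
        sc = builtin_scenarios()[0]

        def inc_qalys(crn: bool) -> np.ndarray:
            pairs = simulate_cohort_pairs(cohort, bundle, seed=21, common_random_numbers=crn)
            accounts = [
                account_pair(p, utility_model, cost_table, pricing, sc.discount_rate)
                for p in pairs
            ]
            return np.array(
                [a.treated.qalys_patient - a.untreated.qalys_patient for a in accounts]
            )

        paired = inc_qalys(True)
        independent = inc_qalys(False)
        assert paired.var(ddof=1) < independent.var(ddof=1)
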