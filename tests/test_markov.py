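"""State spaces, transition rows, the cohort engine and its oracles."""

import itertools

import numpy as np
import pytest

from lungmarkov import (
    cohort_life_expectancy,
    enumerate_states,
    life_expectancy,
    run_cohort,
    survival_at,
    transition_matrix,
    transition_row,
)
from lungmarkov.markov import ARMS

from conftest import flat_curve, symmetric_params


class TestStateSpace:
    def test_state_counts(self):
        assert len(enumerate_states("lobectomy")) == 9
        assert len(enumerate_states("sabr")) == 13

    def test_both_arms_give_22_distinct_states(self):
        states = {
            (s.arm, s.name)
            for arm in ARMS
            for s in enumerate_states(arm).states
        }
        assert len(states) == 22

    def test_names_stable_across_calls(self):
        assert enumerate_states("sabr").names == enumerate_states("sabr").names

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError, match="unknown arm"):
            enumerate_states("wedge_resection")

    def test_single_absorbing_death_per_arm(self):
        for arm in ARMS:
            absorbing = [s for s in enumerate_states(arm).states if s.absorbing]
            assert [s.name for s in absorbing] == ["death"]

    def test_chronic_states_are_not_tunnels(self):
        for arm in ARMS:
            space = enumerate_states(arm)
            for name in space.names:
                if name.startswith("ned") or name == "progression":
                    assert not space.states[space.index(name)].tunnel


class TestTransitionRows:
    @pytest.mark.parametrize("arm", ARMS)
    def test_rows_sum_to_one_for_every_state_and_age(self, base_params, arm):
        space = enumerate_states(arm)
        for age in range(45, 101):
            T = transition_matrix(space, age, base_params)
            np.testing.assert_allclose(T.sum(axis=-1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("arm", ARMS)
    def test_death_receives_at_least_background_mortality(self, base_params, arm):
        space = enumerate_states(arm)
        death = space.index("death")
        for age in (45, 60, 75, 90, 100):
            bg = base_params.bg_mortality(age)
            T = transition_matrix(space, age, base_params)
            alive_states = [i for i, s in enumerate(space.states) if not s.absorbing]
            assert np.all(T[alive_states, death] >= bg - 1e-12)

    def test_death_state_is_a_point_mass(self, base_params):
        space = enumerate_states("sabr")
        row = transition_row(space.states[space.index("death")], 70, base_params)
        expected = np.zeros(len(space))
        expected[space.index("death")] = 1.0
        np.testing.assert_array_equal(row, expected)

    def test_no_transition_out_of_death(self, base_params):
        for arm in ARMS:
            space = enumerate_states(arm)
            T = transition_matrix(space, 60, base_params)
            death = space.index("death")
            off_diag = np.delete(T[death], death)
            assert np.all(off_diag == 0)

    def test_ned_exit_is_competing_risk_of_death_and_progression(self, base_params):
        # independent-risks oracle at the age-85 anchor of the SABR arm
        space = enumerate_states("sabr")
        row = transition_row(space.states[space.index("ned")], 85, base_params)
        stay = row[space.index("ned")]
        assert stay == pytest.approx((1 - 0.082156) * (1 - 0.0790), rel=1e-12)

    def test_lobectomy_failures_have_no_local_component(self, base_params):
        # local-only share of recurrences after lobectomy is 0: every failure
        # leaving NED is regional (salvage track or bridge) or distant
        space = enumerate_states("lobectomy")
        row = transition_row(space.states[space.index("ned")], 70, base_params)
        bg = base_params.bg_mortality(70)
        fail = (1 - bg) * base_params.p_prog_lob.point
        frr = base_params.frac_rr_lob.point
        srr = base_params.p_salv_rr_lob.point
        assert row[space.index("rr_detected")] == pytest.approx(fail * frr * srr, rel=1e-12)
        assert row[space.index("untreated_recurrence")] == pytest.approx(
            fail * frr * (1 - srr), rel=1e-12
        )
        assert row[space.index("progression")] == pytest.approx(
            fail * (1 - frr), rel=1e-12
        )

    def test_distant_salvage_is_not_modelled(self, base_params):
        params = base_params.replace(p_salv_dm=0.1)
        with pytest.raises(ValueError, match="p_salv_dm"):
            transition_matrix(enumerate_states("sabr"), 70, params)

    def test_negative_age_rejected(self, base_params):
        state = enumerate_states("sabr").states[0]
        with pytest.raises(ValueError):
            transition_row(state, -5, base_params)


class TestCohortTrace:
    @pytest.mark.parametrize("arm,age", list(itertools.product(ARMS, (45, 65, 85))))
    def test_trace_invariants(self, base_params, arm, age):
        trace = run_cohort(arm, age, base_params)
        assert trace.occupancy.shape == (16, len(enumerate_states(arm)))
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        death = trace.occupancy[:, trace.states.index("death")]
        assert np.all(np.diff(death) >= -1e-15)
        first = np.zeros(len(trace.states))
        first[trace.states.index("initial")] = 1.0
        np.testing.assert_array_equal(trace.occupancy[0], first)

    def test_immortal_cohort_stays_alive(self, immortal_params):
        for arm in ARMS:
            trace = run_cohort(arm, 60, immortal_params)
            np.testing.assert_allclose(trace.alive, 1.0, atol=1e-15)
            assert life_expectancy(trace) == pytest.approx(15.0)

    def test_certain_perioperative_death(self, lethal_procedure_params):
        for arm in ARMS:
            trace = run_cohort(arm, 60, lethal_procedure_params)
            assert np.all(trace.alive[1:] == 0.0)
            assert life_expectancy(trace) == pytest.approx(0.5)

    def test_start_age_domain(self, base_params):
        with pytest.raises(ValueError):
            run_cohort("sabr", 30, base_params)

    def test_deterministic(self, base_params):
        a = run_cohort("lobectomy", 75, base_params)
        b = run_cohort("lobectomy", 75, base_params)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_export_frame_columns(self, base_params):
        frame = run_cohort("sabr", 70, base_params).to_frame()
        assert "alive" in frame.columns and "attained_age" in frame.columns
        assert list(frame["attained_age"]) == list(range(70, 86))


class TestSurvivalAndLifeExpectancy:
    def test_survival_starts_at_one_and_decreases(self, base_params):
        trace = run_cohort("sabr", 70, base_params)
        assert survival_at(trace, 0) == 1.0
        values = [survival_at(trace, t) for t in np.linspace(0, 15, 61)]
        assert np.all(np.diff(values) <= 1e-15)

    def test_noninteger_times_interpolate_linearly(self, base_params):
        trace = run_cohort("lobectomy", 75, base_params)
        mid = 0.5 * (survival_at(trace, 3) + survival_at(trace, 4))
        assert survival_at(trace, 3.5) == pytest.approx(mid, rel=1e-12)

    def test_out_of_horizon_rejected(self, base_params):
        trace = run_cohort("lobectomy", 75, base_params)
        with pytest.raises(ValueError):
            survival_at(trace, 15.5)

    def test_half_cycle_correction_on_immediate_death(self, lethal_procedure_params):
        trace = run_cohort("sabr", 60, lethal_procedure_params)
        assert life_expectancy(trace) == 0.5

    @pytest.mark.parametrize("arm", ARMS)
    def test_life_expectancy_matches_exhaustive_path_enumeration(self, base_params, arm):
        # brute-force oracle: over a short horizon, enumerate every state
        # path, weight by its probability, and average the per-path
        # half-cycle-corrected alive time
        params = base_params.replace(n_cycles=3)
        space = enumerate_states(arm)
        start_age = 80
        mats = [transition_matrix(space, start_age + t, params) for t in range(3)]
        death = space.index("death")
        expected = 0.0
        init = space.index("initial")
        for path in itertools.product(range(len(space)), repeat=3):
            prob = mats[0][init, path[0]]
            for t in range(1, 3):
                prob *= mats[t][path[t - 1], path[t]]
            if prob == 0.0:
                continue
            s = np.array([1.0] + [float(p != death) for p in path])
            expected += prob * (0.5 * s[0] + s[1:-1].sum() + 0.5 * s[-1])
        got = life_expectancy(run_cohort(arm, start_age, params))
        assert got == pytest.approx(expected, abs=1e-10)


class TestModelProperties:
    @pytest.mark.parametrize(
        "name",
        ["mort_sabr", "mort_progression", "p_prog_lob", "p_prog_sabr",
         "p_prog_post_salv_rr_lob", "p_prog_post_salv_rr_sabr", "mort_conv_rt"],
    )
    def test_raising_any_mortality_or_progression_never_helps(self, base_params, name):
        est = getattr(base_params, name)
        bumped = base_params.replace(**{name: min(1.0, est.point + 0.05)})
        for arm, age in (("lobectomy", 55), ("sabr", 75)):
            le_base = cohort_life_expectancy(arm, age, base_params)
            le_bump = cohort_life_expectancy(arm, age, bumped)
            assert le_bump <= le_base + 1e-12

    def test_raising_background_mortality_never_helps(self, base_params):
        worse = base_params.replace(bg_mortality=base_params.bg_mortality.scaled(1.5))
        for arm in ARMS:
            assert cohort_life_expectancy(arm, 65, worse) <= cohort_life_expectancy(
                arm, 65, base_params
            )

    def test_arm_symmetry_under_equalized_parameters(self, base_params):
        params = symmetric_params(base_params)
        for age in (45, 70, 85):
            le_lob = cohort_life_expectancy("lobectomy", age, params)
            le_sabr = cohort_life_expectancy("sabr", age, params)
            assert abs(le_lob - le_sabr) < 1e-9

    def test_batched_evaluation_matches_scalar(self, base_params):
        values = np.array([0.02, 0.0400, 0.07])
        batch = cohort_life_expectancy("lobectomy", 75, base_params, {"p_prog_lob": values})
        for v, le in zip(values, batch):
            single = cohort_life_expectancy("lobectomy", 75, base_params.replace(p_prog_lob=v))
            assert le == pytest.approx(single, rel=1e-12)
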