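"""Catch-up-growth models: cohort stepping, hazard continuum, lagged trajectories."""

import numpy as np
import pytest

from nutrishock import (
    CohortModel,
    HazardAnchor,
    StateVector,
    TransitionRates,
    ValidationError,
    ZTrajectory,
    hazard_at_z,
    make_categories,
    risk_trajectory,
    step_cohort,
    transition_matrix,
)
from nutrishock.growth import Compartment, CompartmentSpace

INIT = [0.7, 0.15, 0.1, 0.05]


class TestCategories:
    def test_bands_partition_and_ratios_monotone(self, categories):
        assert [c.name for c in categories] == ["healthy", "mild", "moderate", "severe"]
        edges = [(c.z_lo, c.z_hi) for c in categories]
        assert edges[0][0] == -1.0 and edges[1] == (-2.0, -1.0) and edges[2] == (-3.0, -2.0)
        hrs = [c.hazard_ratio for c in categories]
        assert hrs == sorted(hrs)

    def test_invalid_hazard_ratios_rejected(self):
        with pytest.raises(ValidationError, match="healthy"):
            make_categories([1.2, 1.6, 2.6, 6.0])
        with pytest.raises(ValidationError, match="non-decreasing"):
            make_categories([1.0, 2.6, 1.6, 6.0])


class TestCohortStepping:
    def test_zero_rates_leave_state_unchanged(self, categories):
        rates = TransitionRates(worsen=0.0, improve=0.0, baseline_mortality=0.0, tenure_steps=1)
        space = CompartmentSpace(categories, 1)
        state = StateVector.from_category_proportions(space, INIT)
        nxt = step_cohort(state, rates)
        assert np.allclose(nxt.values, state.values)
        assert nxt.cumulative_deaths == 0.0
        assert nxt.time_step_index == 1

    def test_mass_conserved_without_mortality(self, categories):
        rates = TransitionRates(worsen=0.1, improve=0.2, baseline_mortality=0.0, tenure_steps=2)
        space = CompartmentSpace(categories, 2)
        state = StateVector.from_category_proportions(space, INIT)
        for _ in range(50):
            state = step_cohort(state, rates)
        assert state.cumulative_deaths == 0.0
        assert state.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mass_conserved_with_mortality_over_many_steps(self, categories, mild_rates):
        space = CompartmentSpace(categories, mild_rates.tenure_steps)
        state = StateVector.from_category_proportions(space, INIT)
        for _ in range(2000):
            state = step_cohort(state, mild_rates)
        assert abs(state.total_mass - 1.0) < 1e-12
        assert state.cumulative_deaths > 0

    def test_entrant_hazard_strictly_between_origin_and_destination(self, categories):
        space = CompartmentSpace(categories, 2)
        for comp in space.compartments:
            if comp.established:
                continue
            hr = space.hazard_ratio(comp)
            lo, hi = sorted(
                (categories[comp.origin].hazard_ratio, categories[comp.cat].hazard_ratio)
            )
            assert lo < hr < hi

    def test_geometric_entrant_option(self, categories):
        space = CompartmentSpace(categories, 1, entrant_hr="geometric")
        comp = Compartment(cat=2, origin=1, age=0)
        assert space.hazard_ratio(comp) == pytest.approx(np.sqrt(1.6 * 2.6))

    def test_rate_budget_enforced(self, categories):
        rates = TransitionRates(worsen=0.5, improve=0.5, baseline_mortality=0.01, tenure_steps=1)
        space = CompartmentSpace(categories, 1)
        state = StateVector.from_category_proportions(space, INIT)
        with pytest.raises(ValidationError, match="exceed 1"):
            step_cohort(state, rates)

    def test_iteration_matches_transition_matrix_power(self, categories, mild_rates):
        """Explicit flow arithmetic equals the matrix-power route."""
        space = CompartmentSpace(categories, mild_rates.tenure_steps)
        state = StateVector.from_category_proportions(space, INIT)
        v0 = np.concatenate([state.values, [0.0]])
        M = transition_matrix(space, mild_rates)
        n_steps = 37
        for _ in range(n_steps):
            state = step_cohort(state, mild_rates)
        v = np.linalg.matrix_power(M, n_steps) @ v0
        assert np.allclose(v[:-1], state.values, atol=1e-12)
        assert v[-1] == pytest.approx(state.cumulative_deaths, abs=1e-12)

    def test_matrix_matches_hand_built_oracle(self):
        """Brute-force matrix for a tiny two-category system, built by hand."""
        cats = make_categories([1.0, 1.0, 2.0, 2.0])
        rates = TransitionRates(worsen=0.1, improve=0.2, baseline_mortality=0.05, tenure_steps=1)
        space = CompartmentSpace(cats, 1)
        idx = space.index
        n = len(space)
        M = np.zeros((n + 1, n + 1))
        M[n, n] = 1.0
        hrs = [c.hazard_ratio for c in cats]
        for j, comp in enumerate(space.compartments):
            hr = hrs[comp.cat] if comp.established else (hrs[comp.cat] + hrs[comp.origin]) / 2
            d = 0.05 * hr
            w = 0.1 if comp.cat < 3 else 0.0
            i = 0.2 if comp.cat > 0 else 0.0
            M[n, j] += d
            if w:
                M[idx[Compartment(cat=comp.cat + 1, origin=comp.cat, age=0)], j] += w
            if i:
                M[idx[Compartment(cat=comp.cat - 1, origin=comp.cat, age=0)], j] += i
            M[idx[Compartment(cat=comp.cat)], j] += 1 - d - w - i
        assert np.allclose(M, transition_matrix(space, rates))

    def test_everyone_eventually_dies_with_positive_mortality(self, categories):
        rates = TransitionRates(worsen=0.05, improve=0.05, baseline_mortality=0.02, tenure_steps=1)
        model = CohortModel(categories, rates, INIT)
        res = model.simulate(4000, record_every=1000)
        assert res.final_state.cumulative_deaths == pytest.approx(1.0, abs=1e-6)

    def test_model_results_history_and_summary(self, categories, mild_rates):
        model = CohortModel(categories, mild_rates, INIT)
        res = model.simulate(10)
        assert set(res.history["tenure"]) <= {"established", "new_entrant"}
        per_step = res.history.groupby("step")["proportion"].sum()
        deaths = res.deaths.reindex(per_step.index)
        assert np.allclose(per_step + deaths, 1.0, atol=1e-12)
        assert "cumulative deaths" in res.summary()


class TestHazardContinuum:
    def test_anchor_nodes_and_midpoints(self, anchors):
        assert hazard_at_z(-2.5, anchors) == pytest.approx(2.6)
        assert hazard_at_z(-3.0, anchors) == pytest.approx((6.0 + 2.6) / 2)

    def test_extrapolation_rules(self, anchors):
        assert hazard_at_z(-5.0, anchors) == pytest.approx(6.0)  # flat below
        assert hazard_at_z(0.5, anchors) == pytest.approx(1.0)  # healthy above
        assert hazard_at_z(2.0, anchors) == pytest.approx(1.0)

    def test_monotone_non_increasing_in_z(self, anchors):
        grid = np.linspace(-6.0, 3.0, 901)
        vals = hazard_at_z(grid, anchors)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals >= 1.0)

    def test_bad_anchor_sets_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            hazard_at_z(-2.0, [HazardAnchor(-2.5, 2.0)])
        with pytest.raises(ValidationError, match="ordered"):
            hazard_at_z(-2.0, [HazardAnchor(-2.5, 2.0), HazardAnchor(-2.5, 3.0)])
        with pytest.raises(ValidationError, match="non-increasing"):
            hazard_at_z(-2.0, [HazardAnchor(-2.5, 2.0), HazardAnchor(-1.5, 3.0)])


class TestRiskTrajectory:
    def test_constant_z_is_at_equilibrium(self, anchors):
        traj = ZTrajectory(ages=(0.0, 1.0, 2.0, 3.0), z=(-1.5,) * 4)
        risk = risk_trajectory(traj, anchors, lag_half_life=1.0)
        assert np.allclose(risk.hazard, hazard_at_z(-1.5, anchors))

    def test_revisited_z_carries_accumulated_risk(self, anchors):
        """Same Z on the way down and on the way up: the later visit is riskier."""
        traj = ZTrajectory(
            ages=(0.0, 0.5, 1.0, 2.0, 3.5), z=(0.0, -1.5, -3.0, -2.25, -1.5)
        )
        risk = risk_trajectory(traj, anchors, lag_half_life=1.0)
        first = risk.hazard[1]
        second = risk.hazard[4]
        assert first == pytest.approx(hazard_at_z(-1.5, anchors))
        assert second > first

    def test_faltering_tracks_continuum_instantly(self, anchors):
        traj = ZTrajectory(ages=(0.0, 0.5, 1.0), z=(0.0, -1.0, -2.5))
        risk = risk_trajectory(traj, anchors, lag_half_life=2.0)
        assert risk.hazard == risk.hazard_memoryless

    def test_catch_up_hazard_dominates_memoryless(self, anchors):
        traj = ZTrajectory(
            ages=tuple(np.linspace(0, 5, 21)),
            z=tuple(np.concatenate([np.linspace(0, -3, 9), np.linspace(-2.8, -0.5, 12)])),
        )
        risk = risk_trajectory(traj, anchors, lag_half_life=1.5)
        assert all(h >= m - 1e-12 for h, m in zip(risk.hazard, risk.hazard_memoryless))

    def test_vanishing_half_life_is_memoryless(self, anchors):
        traj = ZTrajectory(
            ages=(0.0, 1.0, 2.0, 3.0, 4.0), z=(0.0, -2.0, -3.0, -1.5, -0.5)
        )
        risk = risk_trajectory(traj, anchors, lag_half_life=1e-12)
        assert np.allclose(risk.hazard, risk.hazard_memoryless)

    def test_adult_ramp_adds_late_susceptibility(self, anchors):
        ages = tuple(np.linspace(0, 30, 31))
        traj = ZTrajectory(ages=ages, z=(0.0,) * 31)
        base = risk_trajectory(traj, anchors, lag_half_life=1.0)
        ramped = risk_trajectory(traj, anchors, lag_half_life=1.0, adult_ramp=(18.0, 0.02))
        delta = np.array(ramped.hazard) - np.array(base.hazard)
        assert np.allclose(delta[:19], 0.0)
        assert np.all(np.diff(delta[19:]) > 0)

    def test_bad_inputs_rejected(self, anchors):
        with pytest.raises(ValidationError, match="strictly increasing"):
            ZTrajectory(ages=(0.0, 0.0), z=(0.0, -1.0))
        traj = ZTrajectory(ages=(0.0, 1.0), z=(0.0, -1.0))
        with pytest.raises(ValidationError, match="lag_half_life"):
            risk_trajectory(traj, anchors, lag_half_life=0.0)
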