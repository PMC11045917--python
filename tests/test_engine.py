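"""Cohort engine: initialisation, stepping, conservation, orderings."""

import dataclasses

import numpy as np
import pytest

from prediabetes_bia import (
    AnnualTransitionSet,
    TreatmentEffect,
    apply_risk_reduction,
    build_annual_matrix,
    build_strategy,
    initialize,
    matrix_root_monthly,
    simulate,
    step,
)
from prediabetes_bia.rates import DEATH, PRE, T2D
from prediabetes_bia.strategies import StrategySpec, TreatmentLayer


def _single_layer_strategy(rr: float) -> StrategySpec:
    """One treated layer with a constant risk reduction, no flows."""
    layer = TreatmentLayer("treated", TreatmentEffect(rr, rr), accrues_metformin_cost=True)
    return StrategySpec("metformin", (layer,), (), "treated")


class TestInitialize:
    @pytest.mark.parametrize(
        "name, expected",
        [("poland", 2_051_545), ("saudi_arabia", 1_682_390), ("vietnam", 4_722_885)],
    )
    def test_cohort_enters_in_prediabetes(self, countries, name, expected):
        state = initialize(countries[name], build_strategy("titration"))
        assert state.total_mass == pytest.approx(expected, abs=1.0)
        entry = state.mass[0]
        assert entry[PRE] == state.total_mass
        assert np.all(state.mass[1:] == 0.0)

    def test_zero_prevalence_gives_empty_state(self, poland):
        c = dataclasses.replace(poland, prediabetes_prevalence=0.0)
        assert initialize(c, build_strategy("inaction")).total_mass == 0.0


class TestStep:
    def test_single_step_matches_matrix_vector_product(self, poland):
        """Month-1 T2D inflow equals mass x monthly pre->T2D entry."""
        spec = build_strategy("inaction")
        state = initialize(poland, spec)
        n0 = state.total_mass
        t = AnnualTransitionSet()
        monthly = matrix_root_monthly(build_annual_matrix(t))
        new, incident = step(state, spec, t, month=1)
        assert incident == pytest.approx(n0 * monthly[PRE, T2D], rel=1e-12)
        assert np.allclose(new.mass[0], n0 * monthly[PRE], rtol=1e-12)

    def test_all_zero_state_stays_zero(self, poland):
        c = dataclasses.replace(poland, prediabetes_prevalence=0.0)
        spec = build_strategy("ilc")
        state = initialize(c, spec)
        new, incident = step(state, spec, AnnualTransitionSet(), month=1)
        assert new.total_mass == 0.0 and incident == 0.0

    def test_month_zero_rejected(self, poland):
        spec = build_strategy("inaction")
        with pytest.raises(ValueError):
            step(initialize(poland, spec), spec, AnnualTransitionSet(), month=0)


class TestSimulate:
    def test_fifteen_year_run_records_181_states(self, poland_trajectories):
        assert poland_trajectories["inaction"].occupancy.shape[0] == 181

    def test_horizon_zero_is_initial_state_only(self, poland):
        traj = simulate(poland, build_strategy("inaction"), 0)
        assert traj.horizon_months == 0
        assert traj.cumulative_total_expenditure(0) == 0.0

    def test_mass_conservation_over_full_horizon(self, poland_trajectories):
        for traj in poland_trajectories.values():
            totals = traj.occupancy.sum(axis=(1, 2))
            assert np.max(np.abs(totals - totals[0])) < 1e-6 * totals[0]

    def test_death_mass_nondecreasing(self, poland_trajectories):
        for traj in poland_trajectories.values():
            deaths = traj.occupancy[:, :, DEATH].sum(axis=1)
            assert np.all(np.diff(deaths) >= -1e-9)

    def test_incident_t2d_nonnegative(self, poland_trajectories):
        for traj in poland_trajectories.values():
            assert np.all(traj.incident_t2d >= 0.0)

    def test_no_backflow_out_of_t2d(self):
        """T2D leaks only to death: occupancy + cumulative deaths from T2D grow."""
        m = matrix_root_monthly(build_annual_matrix(AnnualTransitionSet()))
        assert m[T2D, PRE] == 0.0 and m[T2D, 0] == 0.0

    def test_monthly_stepping_matches_annual_matrix_for_inaction(self, poland):
        """Whole-year occupancy within 0.1% of the annual-matrix chain."""
        traj = simulate(poland, build_strategy("inaction"), 10)
        annual = build_annual_matrix(AnnualTransitionSet())
        v = np.zeros(4)
        v[PRE] = traj.occupancy[0].sum()
        for year in range(1, 11):
            v = v @ annual
            got = traj.state_totals(12 * year)
            assert np.allclose(got, v, rtol=1e-3, atol=1e-6 * v.sum())

    def test_cumulative_t2d_monotone_in_risk_reduction(self, poland):
        """Larger risk reduction never increases cumulative T2D incidence."""
        cums = [
            simulate(poland, _single_layer_strategy(rr), 5).cumulative_incident_t2d(60)
            for rr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert all(a > b for a, b in zip(cums, cums[1:]))

    def test_intervention_beats_inaction_every_month(self, poland_trajectories):
        inaction = poland_trajectories["inaction"]
        met = poland_trajectories["metformin"]
        for m in range(1, 181):
            assert met.cumulative_incident_t2d(m) < inaction.cumulative_incident_t2d(m)

    def test_year5_strategy_ordering(self, poland_trajectories):
        """Cumulative incidence: titration < combination < ILC < metformin < inaction."""
        cum = {k: t.cumulative_incident_t2d(60) for k, t in poland_trajectories.items()}
        assert (
            cum["titration"]
            < cum["combination"]
            < cum["ilc"]
            < cum["metformin"]
            < cum["inaction"]
        )

    def test_tidy_export_shape(self, poland):
        traj = simulate(poland, build_strategy("metformin"), 1)
        frame = traj.to_frame()
        assert len(frame) == 13 * 2 * 4  # months x layers x states
        assert set(frame.columns) >= {"month", "layer", "state", "mass"}
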