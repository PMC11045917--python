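"""Attributable-fraction costing, the cycle ledger and inaction comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prediabetes_bia import (
    accrue_cycle_costs,
    attributable_split,
    build_strategy,
    compare_to_inaction,
    derive_state_costs,
    simulate,
)
from prediabetes_bia.costing import CostDerivationBand, CostDerivationInputs, uniform_inputs
from prediabetes_bia.rates import PRE, T2D, TreatmentEffect


class TestStateCostDerivation:
    @pytest.mark.parametrize(
        "base, expected",
        [(1499, (1559, 4497)), (354, (368, 1062))],  # Poland, Vietnam triples
    )
    def test_published_triples_reproduced(self, base, expected):
        sc = derive_state_costs(base_percap=base)
        assert round(sc.prediabetes_per_year) == expected[0]
        assert round(sc.t2d_per_year) == expected[1]
        assert sc.normoglycemia_per_year == base

    def test_unit_ratio_means_equal_costs(self):
        sc = derive_state_costs(base_percap=1000, r_prediabetes=1.0, r_t2d=1.0)
        assert sc.prediabetes_per_year == sc.t2d_per_year == 1000

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            CostDerivationBand(1e6, 1e9, 0.1, 0.9)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_state_costs()

    @settings(derandomize=True, max_examples=40)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(1e4, 1e7),  # population
                st.floats(100, 5000),  # base per-capita spend
                st.floats(0.0, 0.5),  # prevalence
                st.floats(1.0, 5.0),  # ratio
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_total_spend_conserved(self, data):
        """N*[P*disease + (1-P)*nondisease] recovers each band's total spend."""
        bands = tuple(
            CostDerivationBand(n, n * base * (1 + p * (r - 1)), p, r)
            for n, base, p, r in data
        )
        inputs = CostDerivationInputs(bands)
        split = attributable_split(inputs)
        for b, dis, nd in zip(
            bands, split.percap_disease_by_band, split.percap_nondisease_by_band
        ):
            recovered = b.population * (b.prevalence * dis + (1 - b.prevalence) * nd)
            assert recovered == pytest.approx(b.resource_use, rel=1e-12)

    def test_multiband_weighted_average(self):
        """Band with more disease mass dominates the weighted disease cost."""
        cheap = CostDerivationBand(1e6, 1e6 * 100 * (1 + 0.1 * 2), 0.1, 3.0)
        dear = CostDerivationBand(1e6, 1e6 * 1000 * (1 + 0.4 * 2), 0.4, 3.0)
        split = attributable_split(CostDerivationInputs((cheap, dear)))
        # prevalence weights 0.1 vs 0.4 -> weighted mean of 300 and 3000
        assert split.percap_disease == pytest.approx((0.1 * 300 + 0.4 * 3000) / 0.5)


class TestCycleLedger:
    def test_t2d_medical_cost_example(self, poland):
        spec = build_strategy("inaction")
        mass = np.zeros((1, 4))
        mass[0, T2D] = 1000.0
        medical, intervention = accrue_cycle_costs(mass, spec, poland)
        assert medical[T2D] == pytest.approx(1000 * 4497 / 12)
        assert intervention == 0.0

    def test_treated_prediabetes_accrues_both_components(self, poland):
        spec = build_strategy("metformin")
        mass = np.zeros((2, 4))
        mass[0, PRE] = 1000.0  # on_metformin layer
        medical, intervention = accrue_cycle_costs(mass, spec, poland)
        assert intervention == pytest.approx(1000 * 5.29)
        assert medical[PRE] == pytest.approx(1000 * 1559 / 12)

    def test_death_accrues_nothing(self, poland):
        spec = build_strategy("ilc")
        mass = np.zeros((2, 4))
        mass[:, 3] = 500.0
        medical, intervention = accrue_cycle_costs(mass, spec, poland)
        assert medical.sum() == 0.0 and intervention == 0.0

    def test_normoglycemic_members_accrue_no_intervention_cost(self, poland):
        spec = build_strategy("ilc")
        mass = np.zeros((2, 4))
        mass[0, 0] = 1000.0  # on_ilc layer, normoglycemia state
        _, intervention = accrue_cycle_costs(mass, spec, poland)
        assert intervention == 0.0

    def test_ledger_additivity(self, poland_trajectories):
        """Cumulative total equals the sum of monthly medical + intervention."""
        traj = poland_trajectories["titration"]
        total = traj.cumulative_total_expenditure(180)
        assert total == pytest.approx(
            traj.medical_by_state.sum() + traj.intervention_cost.sum()
        )
        assert np.all(traj.medical_by_state >= 0.0)
        assert np.all(traj.intervention_cost >= 0.0)


class TestCompareToInaction:
    def test_inaction_vs_itself_is_zero(self, poland_trajectories):
        inaction = poland_trajectories["inaction"]
        for r in compare_to_inaction(inaction, inaction, [1, 5, 10, 15]):
            assert r.total_expenditure_difference == 0.0
            assert r.t2d_cost_saving == 0.0
            assert r.percent_change_incident == 0.0

    def test_effective_strategies_save_t2d_costs_at_all_horizons(
        self, poland_trajectories
    ):
        inaction = poland_trajectories["inaction"]
        for kind in ("metformin", "ilc", "combination", "titration"):
            for r in compare_to_inaction(
                poland_trajectories[kind], inaction, [1, 5, 10, 15]
            ):
                assert r.t2d_cost_saving < 0.0
                assert r.prevalent_t2d_difference < 0.0

    def test_zero_effect_with_positive_cost_is_pure_loss(self, poland):
        none = TreatmentEffect(0.0, 0.0)
        inaction = simulate(poland, build_strategy("inaction"), 5)
        traj = simulate(
            poland, build_strategy("ilc", metformin_effect=none, ilc_effect=none), 5
        )
        for r in compare_to_inaction(traj, inaction, [1, 5]):
            assert r.total_expenditure_difference > 0.0

    def test_mismatched_countries_rejected(self, poland, vietnam):
        a = simulate(poland, build_strategy("inaction"), 1)
        b = simulate(vietnam, build_strategy("inaction"), 1)
        with pytest.raises(ValueError):
            compare_to_inaction(a, b, [1])


def test_uniform_inputs_reduce_to_ratio_times_base():
    split = attributable_split(uniform_inputs(500.0, 3.0, prevalence=0.25))
    assert split.percap_nondisease == pytest.approx(500.0)
    assert split.percap_disease == pytest.approx(1500.0)
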