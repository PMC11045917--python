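"""One-way sensitivity analyses (OWSA) around the base case.

Each scenario perturbs exactly one input family, re-runs the simulation,
and reports the percent change in year-5 cumulative total health care
expenditure relative to that strategy's own base case:

* disease-state costs x0.8 / x1.2,
* intervention costs x0.8 / x1.2,
* intervention effect x0.8 / x1.2 (both risk-reduction regimes, capped at 1),
* combination effect +20% (the ILC-carried effect in the combination and
  titration arms only),
* ILC cost removal (the lifestyle programme is costless to the payer).

The headline "average effect" is the unweighted mean of percent changes
across the four treatment strategies (intervention arms; inaction is its
own base case and is unaffected by every scenario except disease-state
cost).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import pandas as pd

from .engine import DEFAULT_TRANSITIONS, simulate
from .params import CountryParameters, InterventionCosts, StateCosts
from .rates import ILC_EFFECT, METFORMIN_EFFECT, AnnualTransitionSet, TreatmentEffect
from .strategies import AdherenceParameters, build_strategy

logger = logging.getLogger(__name__)

PARAMETER_TARGETS = (
    "disease_state_cost",
    "intervention_cost",
    "intervention_effect",
    "combination_effect",
    "ilc_cost_removal",
)
TREATMENT_STRATEGIES = ("metformin", "ilc", "combination", "titration")
ILC_STRATEGIES = ("ilc", "combination", "titration")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    parameter_target: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.parameter_target not in PARAMETER_TARGETS:
            raise ValueError(f"unknown parameter target {self.parameter_target!r}")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


DEFAULT_SCENARIOS = (
    ScenarioSpec("disease_state_cost_-20", "disease_state_cost", 0.8),
    ScenarioSpec("disease_state_cost_+20", "disease_state_cost", 1.2),
    ScenarioSpec("intervention_cost_-20", "intervention_cost", 0.8),
    ScenarioSpec("intervention_cost_+20", "intervention_cost", 1.2),
    ScenarioSpec("intervention_effect_-20", "intervention_effect", 0.8),
    ScenarioSpec("intervention_effect_+20", "intervention_effect", 1.2),
    ScenarioSpec("combination_effect_+20", "combination_effect", 1.2),
    ScenarioSpec("ilc_cost_removal", "ilc_cost_removal", 0.0),
)


def _scale_state_costs(costs: StateCosts, k: float) -> StateCosts:
    return dataclasses.replace(
        costs,
        normoglycemia_per_year=costs.normoglycemia_per_year * k,
        prediabetes_per_year=costs.prediabetes_per_year * k,
        t2d_per_year=costs.t2d_per_year * k,
    )


def _scaled_effect(effect: TreatmentEffect, k: float, label: str) -> TreatmentEffect:
    if max(effect.rr_early, effect.rr_late) * k > 1.0:
        logger.warning("%s: scaled risk reduction exceeds 1, capping", label)
    return effect.scaled(k)


def _perturb(
    country: CountryParameters,
    strategy_kind: str,
    scenario: ScenarioSpec,
    adherence: AdherenceParameters,
):
    """Return (country', strategy spec') with the scenario applied."""
    met_eff, ilc_eff = METFORMIN_EFFECT, ILC_EFFECT
    target, k = scenario.parameter_target, scenario.multiplier

    if target == "disease_state_cost":
        country = dataclasses.replace(
            country, state_costs=_scale_state_costs(country.state_costs, k)
        )
    elif target == "intervention_cost":
        ic = country.intervention_costs
        country = dataclasses.replace(
            country,
            intervention_costs=InterventionCosts(
                metformin_per_month=ic.metformin_per_month * k,
                ilc_per_month=ic.ilc_per_month * k,
            ),
        )
    elif target == "ilc_cost_removal":
        ic = country.intervention_costs
        country = dataclasses.replace(
            country,
            intervention_costs=InterventionCosts(
                metformin_per_month=ic.metformin_per_month,
                ilc_per_month=ic.ilc_per_month * k,
            ),
        )
    elif target == "intervention_effect":
        met_eff = _scaled_effect(met_eff, k, scenario.name)
        ilc_eff = _scaled_effect(ilc_eff, k, scenario.name)
    elif target == "combination_effect":
        # boosts only the ILC-carried effect inside combination/titration arms
        if strategy_kind in ("combination", "titration"):
            ilc_eff = _scaled_effect(ilc_eff, k, scenario.name)

    spec = build_strategy(
        strategy_kind, adherence, metformin_effect=met_eff, ilc_effect=ilc_eff
    )
    return country, spec


def run_owsa(
    country: CountryParameters,
    strategies: tuple[str, ...] = TREATMENT_STRATEGIES,
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS,
    horizon_years: int = 5,
    adherence: AdherenceParameters | None = None,
    transitions: AnnualTransitionSet = DEFAULT_TRANSITIONS,
) -> pd.DataFrame:
    """Percent change in cumulative total expenditure vs each strategy's base.

    Returns a long-format frame with columns ``country``, ``strategy``,
    ``scenario``, ``percent_change`` (in percent).
    """
    adherence = adherence or AdherenceParameters()
    month = 12 * horizon_years
    rows = []
    for kind in strategies:
        base_spec = build_strategy(kind, adherence)
        base = simulate(country, base_spec, horizon_years, transitions)
        base_total = base.cumulative_total_expenditure(month)
        for scenario in scenarios:
            c2, s2 = _perturb(country, kind, scenario, adherence)
            traj = simulate(c2, s2, horizon_years, transitions)
            total = traj.cumulative_total_expenditure(month)
            change = 100.0 * (total - base_total) / base_total if base_total else 0.0
            rows.append(
                {
                    "country": country.name,
                    "strategy": kind,
                    "scenario": scenario.name,
                    "percent_change": change,
                }
            )
    return pd.DataFrame(rows)


def owsa_summary(table: pd.DataFrame, strategies: tuple[str, ...] = TREATMENT_STRATEGIES) -> pd.DataFrame:
    """Unweighted mean percent change per scenario across treatment arms."""
    sub = table[table["strategy"].isin(strategies)]
    return (
        sub.groupby(["country", "scenario"], as_index=False)["percent_change"]
        .mean()
        .rename(columns={"percent_change": "mean_percent_change"})
    )
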