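"""Attributable-fraction state costing and the per-cycle cost ledger.

Disease-state medical costs follow the relative-cost-ratio ("R rate")
method: per-capita annual spend for people in a disease state is R times
the spend of people without the disease, with the split chosen so that
total observed health expenditure is conserved. For an age band with
population N_a, total projected resource use U_a, disease prevalence P_a
and ratio R_a,

    percap_nondisease_a = U_a / (N_a * (1 + P_a * (R_a - 1)))
    percap_disease_a    = R_a * percap_nondisease_a

which guarantees N_a * [P_a * disease + (1 - P_a) * nondisease] = U_a.
Country-level state costs are prevalence-weighted averages across bands;
with a single band this collapses to cost_state = R * cost_normoglycemia.
The base case uses R = 1.04 for prediabetes and R = 3 for T2D.

During simulation, each monthly cycle accrues one twelfth of the annual
state cost for every living member (death costs nothing) plus intervention
costs for prediabetic members of treated layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CountryParameters, StateCosts
from .rates import DEATH, N_STATES, PRE, T2D
from .strategies import StrategySpec


@dataclass(frozen=True)
class CostDerivationBand:
    """One age band's inputs to the attributable-fraction split (one disease)."""

    population: float
    resource_use: float  # U_a: total projected health resource use, currency
    prevalence: float  # P_a
    ratio: float  # R_a

    def __post_init__(self) -> None:
        if self.population < 0 or self.resource_use < 0:
            raise ValueError("population and resource use must be >= 0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        if self.ratio < 1.0:
            raise ValueError(f"relative cost ratio {self.ratio} must be >= 1")


@dataclass(frozen=True)
class CostDerivationInputs:
    bands: tuple[CostDerivationBand, ...]


@dataclass(frozen=True)
class AttributableSplit:
    percap_disease_by_band: tuple[float, ...]
    percap_nondisease_by_band: tuple[float, ...]
    percap_disease: float  # prevalence-weighted across bands
    percap_nondisease: float  # non-disease-population-weighted across bands


def attributable_split(inputs: CostDerivationInputs) -> AttributableSplit:
    """Split each band's total spend into disease/non-disease per-capita costs."""
    dis, nondis, w_dis, w_non = [], [], [], []
    for b in inputs.bands:
        nd = b.resource_use / (b.population * (1.0 + b.prevalence * (b.ratio - 1.0)))
        nondis.append(nd)
        dis.append(b.ratio * nd)
        w_dis.append(b.population * b.prevalence)
        w_non.append(b.population * (1.0 - b.prevalence))
    dis_w = float(np.average(dis, weights=w_dis)) if sum(w_dis) > 0 else float("nan")
    non_w = float(np.average(nondis, weights=w_non)) if sum(w_non) > 0 else float("nan")
    return AttributableSplit(tuple(dis), tuple(nondis), dis_w, non_w)


def uniform_inputs(
    base_percap: float,
    ratio: float,
    prevalence: float = 0.1,
    population: float = 1e6,
) -> CostDerivationInputs:
    """Single-band inputs whose non-disease per-capita cost equals base_percap.

    Total resource use is set to N * base * (1 + P*(R-1)), i.e. the spend a
    population with the given prevalence and ratio would generate, so the
    split returns exactly (R * base, base).
    """
    u = population * base_percap * (1.0 + prevalence * (ratio - 1.0))
    return CostDerivationInputs(
        (CostDerivationBand(population, u, prevalence, ratio),)
    )


def derive_state_costs(
    prediabetes_inputs: CostDerivationInputs | None = None,
    t2d_inputs: CostDerivationInputs | None = None,
    *,
    base_percap: float | None = None,
    r_prediabetes: float = 1.04,
    r_t2d: float = 3.0,
) -> StateCosts:
    """Derive the annual per-capita cost triple via the R-rate method.

    Either pass per-band derivation inputs for each disease, or just
    ``base_percap`` (the normoglycemia per-capita annual cost) to use the
    single-band uniform reduction cost_state = R * base_percap.
    """
    if base_percap is None and (prediabetes_inputs is None or t2d_inputs is None):
        raise ValueError("provide base_percap or derivation inputs for both diseases")
    if prediabetes_inputs is None:
        prediabetes_inputs = uniform_inputs(base_percap, r_prediabetes)
    if t2d_inputs is None:
        t2d_inputs = uniform_inputs(base_percap, r_t2d)

    pre_split = attributable_split(prediabetes_inputs)
    t2d_split = attributable_split(t2d_inputs)
    normo = base_percap if base_percap is not None else t2d_split.percap_nondisease
    return StateCosts(
        normoglycemia_per_year=normo,
        prediabetes_per_year=pre_split.percap_disease,
        t2d_per_year=t2d_split.percap_disease,
        r_prediabetes=r_prediabetes,
        r_t2d=r_t2d,
    )


def accrue_cycle_costs(
    mass: np.ndarray,
    spec: StrategySpec,
    country: CountryParameters,
) -> tuple[np.ndarray, float]:
    """One cycle's costs for an occupancy array of shape (layers, states).

    Returns ``(medical_by_state, intervention_total)``: medical cost is one
    twelfth of the annual state cost for every living member regardless of
    layer (death accrues nothing); intervention cost is charged on the
    prediabetes-state mass of layers flagged for metformin and/or ILC.
    """
    mass = np.asarray(mass, dtype=float)
    monthly_state_cost = country.state_costs.as_annual_vector() / 12.0
    medical_by_state = mass.sum(axis=0) * monthly_state_cost
    medical_by_state[DEATH] = 0.0

    intervention = 0.0
    costs = country.intervention_costs
    for i, layer in enumerate(spec.layers):
        if layer.accrues_metformin_cost:
            intervention += mass[i, PRE] * costs.metformin_per_month
        if layer.accrues_ilc_cost:
            intervention += mass[i, PRE] * costs.ilc_per_month
    return medical_by_state, intervention


@dataclass(frozen=True)
class ComparativeResult:
    """Strategy-vs-inaction comparison at one horizon (negative = saving)."""

    horizon_years: int
    t2d_cost_saving: float  # cumulative T2D-state medical cost difference
    total_expenditure_difference: float  # cumulative medical + intervention
    percent_difference: float  # total difference / inaction total
    prevalent_t2d_difference: float  # T2D occupancy difference at horizon
    incident_t2d_difference: float  # cumulative entrants difference
    percent_change_incident: float  # incident difference / inaction incident


def compare_to_inaction(strategy_traj, inaction_traj, horizons) -> list[ComparativeResult]:
    """Comparative outputs at each horizon (years) against the inaction run."""
    if strategy_traj.country_name != inaction_traj.country_name:
        raise ValueError("trajectories are for different countries")
    results = []
    for h in horizons:
        m = 12 * h
        if m > strategy_traj.horizon_months or m > inaction_traj.horizon_months:
            raise ValueError(f"horizon {h}y exceeds simulated trajectory")
        inaction_total = inaction_traj.cumulative_total_expenditure(m)
        diff_total = strategy_traj.cumulative_total_expenditure(m) - inaction_total
        inaction_inc = inaction_traj.cumulative_incident_t2d(m)
        diff_inc = strategy_traj.cumulative_incident_t2d(m) - inaction_inc
        results.append(
            ComparativeResult(
                horizon_years=h,
                t2d_cost_saving=(
                    strategy_traj.cumulative_medical_by_state(m)[T2D]
                    - inaction_traj.cumulative_medical_by_state(m)[T2D]
                ),
                total_expenditure_difference=diff_total,
                percent_difference=diff_total / inaction_total if inaction_total else 0.0,
                prevalent_t2d_difference=(
                    strategy_traj.prevalent_t2d(m) - inaction_traj.prevalent_t2d(m)
                ),
                incident_t2d_difference=diff_inc,
                percent_change_incident=diff_inc / inaction_inc if inaction_inc else 0.0,
            )
        )
    return results
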