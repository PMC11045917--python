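"""Monthly-cycle cohort engine over (treatment layer x health state) mass.

The whole prevalent prediabetes cohort enters the model in the prediabetes
state of the strategy's entry layer and is propagated deterministically
for 12 x horizon monthly cycles. Each cycle:

1. every layer's mass vector is multiplied by that layer's monthly
   transition matrix — the eigen-decomposition 12th root of the annual
   matrix with the layer's currently active risk reduction applied to the
   prediabetes -> T2D probability (two regimes: months 1-36 and beyond);
2. adherence flows then move a monthly constant-hazard fraction of the
   *prediabetes-state* mass between layers (defaulting is an adherence
   event among still-prediabetic patients);
3. the cycle's costs are accrued on the end-of-cycle occupancy.

The cohort is closed: no entrants, death is an ordinary (absorbing) state,
and total mass is conserved to machine precision — a relative drift above
1e-6 raises, since it can only be an implementation bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing
from .params import CountryParameters
from .rates import (
    DEATH,
    N_STATES,
    PRE,
    STATES,
    T2D,
    AnnualTransitionSet,
    apply_risk_reduction,
    build_annual_matrix,
    matrix_root_monthly,
    scalar_prob_to_monthly,
)
from .strategies import StrategySpec

DEFAULT_TRANSITIONS = AnnualTransitionSet()
_CONSERVATION_RTOL = 1e-6


@dataclass
class CohortState:
    """Occupancy mass (persons, real-valued) per (layer, health state)."""

    month: int
    layers: tuple[str, ...]
    mass: np.ndarray  # shape (n_layers, 4)

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (len(self.layers), N_STATES):
            raise ValueError("mass shape does not match layers x states")
        if np.any(self.mass < -1e-9):
            raise ValueError("negative occupancy mass")

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def state_totals(self) -> np.ndarray:
        """Mass per health state summed over layers."""
        return self.mass.sum(axis=0)


@dataclass
class CohortTrajectory:
    """Recorded monthly occupancy, T2D incidence and cost ledger.

    Arrays are indexed by month 0..H; month 0 is the initial state and
    accrues no incidence or cost.
    """

    country_name: str
    strategy_kind: str
    layers: tuple[str, ...]
    occupancy: np.ndarray  # (H+1, n_layers, 4)
    incident_t2d: np.ndarray  # (H+1,), entrants to T2D during each month
    medical_by_state: np.ndarray  # (H+1, 4) cost accrued that month
    intervention_cost: np.ndarray  # (H+1,)

    @property
    def horizon_months(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_totals(self, month: int) -> np.ndarray:
        return self.occupancy[month].sum(axis=0)

    def prevalent_t2d(self, month: int) -> float:
        return float(self.state_totals(month)[T2D])

    def cumulative_incident_t2d(self, month: int) -> float:
        return float(self.incident_t2d[: month + 1].sum())

    def cumulative_medical_by_state(self, month: int) -> np.ndarray:
        return self.medical_by_state[: month + 1].sum(axis=0)

    def cumulative_medical(self, month: int) -> float:
        return float(self.cumulative_medical_by_state(month).sum())

    def cumulative_intervention(self, month: int) -> float:
        return float(self.intervention_cost[: month + 1].sum())

    def cumulative_total_expenditure(self, month: int) -> float:
        return self.cumulative_medical(month) + self.cumulative_intervention(month)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (month, layer, state)."""
        rows = []
        for m in range(self.horizon_months + 1):
            for i, layer in enumerate(self.layers):
                for s, state in enumerate(STATES):
                    rows.append(
                        {
                            "month": m,
                            "layer": layer,
                            "state": state,
                            "mass": self.occupancy[m, i, s],
                        }
                    )
        frame = pd.DataFrame(rows)
        frame["strategy"] = self.strategy_kind
        frame["country"] = self.country_name
        return frame


def initialize(country: CountryParameters, spec: StrategySpec) -> CohortState:
    """Place the full prevalent prediabetes cohort in the entry layer."""
    from .params import prevalent_prediabetes_cohort

    layers = tuple(l.name for l in spec.layers)
    mass = np.zeros((len(layers), N_STATES))
    mass[spec.layer_index(spec.entry_layer), PRE] = prevalent_prediabetes_cohort(country)
    return CohortState(month=0, layers=layers, mass=mass)


class _MatrixCache:
    """Monthly matrices keyed by active risk reduction (two regimes/layer)."""

    def __init__(self, transitions: AnnualTransitionSet):
        self.transitions = transitions
        self._cache: dict[float, np.ndarray] = {}

    def monthly(self, rr: float) -> np.ndarray:
        if rr not in self._cache:
            annual = build_annual_matrix(apply_risk_reduction(self.transitions, rr))
            self._cache[rr] = matrix_root_monthly(annual)
        return self._cache[rr]


def step(
    state: CohortState,
    spec: StrategySpec,
    transitions: AnnualTransitionSet,
    month: int,
    cache: _MatrixCache | None = None,
) -> tuple[CohortState, float]:
    """Advance one monthly cycle; returns (new state, incident T2D mass)."""
    if month < 1:
        raise ValueError("month must be >= 1")
    cache = cache or _MatrixCache(transitions)
    before = state.total_mass

    new_mass = np.empty_like(state.mass)
    incident = 0.0
    for i, layer in enumerate(spec.layers):
        rr = 0.0 if layer.effect is None else layer.effect.at_month(month)
        m = cache.monthly(rr)
        v = state.mass[i]
        nv = v @ m
        incident += float(nv[T2D] - v[T2D] * m[T2D, T2D])  # inflow into T2D
        new_mass[i] = nv

    # adherence flows act on prediabetes-state mass, simultaneously
    delta = np.zeros(len(spec.layers))
    for f in spec.flows:
        q = scalar_prob_to_monthly(f.annual_probability)
        amount = new_mass[spec.layer_index(f.from_layer), PRE] * q
        delta[spec.layer_index(f.from_layer)] -= amount
        delta[spec.layer_index(f.to_layer)] += amount
    new_mass[:, PRE] += delta

    after = float(new_mass.sum())
    if abs(after - before) > _CONSERVATION_RTOL * max(before, 1.0):
        raise RuntimeError(
            f"mass conservation violated at month {month}: {before} -> {after}"
        )
    return CohortState(month=month, layers=state.layers, mass=new_mass), incident


def simulate(
    country: CountryParameters,
    spec: StrategySpec,
    horizon_years: int,
    transitions: AnnualTransitionSet = DEFAULT_TRANSITIONS,
) -> CohortTrajectory:
    """Run the cohort for 12 x horizon_years monthly cycles.

    Costs are accrued on each cycle's end-of-cycle occupancy (no half-cycle
    correction); month 0 carries no cost or incidence.
    """
    if horizon_years < 0:
        raise ValueError("horizon must be >= 0")
    n_months = 12 * horizon_years
    state = initialize(country, spec)
    cache = _MatrixCache(transitions)

    occupancy = np.zeros((n_months + 1, len(spec.layers), N_STATES))
    incident = np.zeros(n_months + 1)
    medical = np.zeros((n_months + 1, N_STATES))
    intervention = np.zeros(n_months + 1)

    occupancy[0] = state.mass
    for m in range(1, n_months + 1):
        state, inc = step(state, spec, transitions, m, cache)
        occupancy[m] = state.mass
        incident[m] = inc
        medical[m], intervention[m] = costing.accrue_cycle_costs(
            state.mass, spec, country
        )
    return CohortTrajectory(
        country_name=country.name,
        strategy_kind=spec.kind,
        layers=state.layers,
        occupancy=occupancy,
        incident_t2d=incident,
        medical_by_state=medical,
        intervention_cost=intervention,
    )
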