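"""Intervention strategies as layered sub-cohorts with defaulting flows.

Each strategy is a small directed acyclic graph of treatment layers. A
layer carries an optional treatment effect (the two-regime annual T2D risk
reduction) and flags for which intervention costs its prediabetic members
accrue. Flows between layers model adherence: an annual defaulting
probability, converted to a monthly constant hazard, moves prediabetic
mass from one layer to the next each cycle.

The five strategies:

* ``inaction`` — one untreated layer, no flows.
* ``metformin`` — on-metformin layer; 10%/yr noncompliance to inaction.
* ``ilc`` — on-ILC layer; 51%/yr defaulting straight to inaction.
* ``combination`` — ILC + metformin together (ILC-level effect, both
  costs); ILC defaulters keep metformin alone, whose noncompliers move to
  inaction.
* ``titration`` — start on ILC alone; ILC defaulters get metformin added
  (keeping ILC-level effect and both costs); a second ILC default leaves
  metformin alone, then inaction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rates import ILC_EFFECT, METFORMIN_EFFECT, TreatmentEffect

STRATEGY_KINDS = ("inaction", "metformin", "ilc", "combination", "titration")


@dataclass(frozen=True)
class AdherenceParameters:
    """Annual persistence probabilities: metformin compliance 90%, ILC usage 49%."""

    metformin_compliance_annual: float = 0.90
    ilc_usage_annual: float = 0.49

    def __post_init__(self) -> None:
        for name in ("metformin_compliance_annual", "ilc_usage_annual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TreatmentLayer:
    name: str
    effect: TreatmentEffect | None = None
    accrues_metformin_cost: bool = False
    accrues_ilc_cost: bool = False

    def __post_init__(self) -> None:
        if self.effect is None and (self.accrues_metformin_cost or self.accrues_ilc_cost):
            raise ValueError(f"untreated layer {self.name!r} cannot accrue intervention cost")


@dataclass(frozen=True)
class LayerFlow:
    from_layer: str
    to_layer: str
    annual_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_probability <= 1.0:
            raise ValueError("flow probability outside [0, 1]")


@dataclass(frozen=True)
class StrategySpec:
    kind: str
    layers: tuple[TreatmentLayer, ...]
    flows: tuple[LayerFlow, ...]
    entry_layer: str

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        if self.entry_layer not in names:
            raise ValueError(f"entry layer {self.entry_layer!r} not among layers")
        outflow: dict[str, float] = {}
        for f in self.flows:
            if f.from_layer not in names or f.to_layer not in names:
                raise ValueError(f"flow references unknown layer: {f}")
            outflow[f.from_layer] = outflow.get(f.from_layer, 0.0) + f.annual_probability
        for layer, total in outflow.items():
            if total > 1.0 + 1e-12:
                raise ValueError(f"annual outflow from layer {layer!r} sums to {total} > 1")
        self._check_acyclic(names)

    def _check_acyclic(self, names: list[str]) -> None:
        adj = {n: [] for n in names}
        for f in self.flows:
            adj[f.from_layer].append(f.to_layer)
        seen: dict[str, int] = {}  # 1=in progress, 2=done

        def visit(n: str) -> None:
            if seen.get(n) == 1:
                raise ValueError("layer flow graph has a cycle")
            if seen.get(n) == 2:
                return
            seen[n] = 1
            for m in adj[n]:
                visit(m)
            seen[n] = 2

        for n in names:
            visit(n)

    def layer(self, name: str) -> TreatmentLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"unknown layer {name!r}")

    def layer_index(self, name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == name:
                return i
        raise KeyError(f"unknown layer {name!r}")


def build_strategy(
    kind: str,
    adherence: AdherenceParameters | None = None,
    metformin_effect: TreatmentEffect = METFORMIN_EFFECT,
    ilc_effect: TreatmentEffect = ILC_EFFECT,
) -> StrategySpec:
    """Construct the layer graph for one of the five strategy kinds."""
    adherence = adherence or AdherenceParameters()
    q_met = 1.0 - adherence.metformin_compliance_annual
    q_ilc = 1.0 - adherence.ilc_usage_annual

    inaction = TreatmentLayer("inaction")
    on_met = TreatmentLayer("on_metformin", metformin_effect, accrues_metformin_cost=True)
    on_ilc = TreatmentLayer("on_ilc", ilc_effect, accrues_ilc_cost=True)
    on_both = TreatmentLayer(
        "on_both", ilc_effect, accrues_metformin_cost=True, accrues_ilc_cost=True
    )
    met_only = TreatmentLayer("metformin_only", metformin_effect, accrues_metformin_cost=True)

    if kind == "inaction":
        return StrategySpec(kind, (inaction,), (), "inaction")
    if kind == "metformin":
        return StrategySpec(
            kind,
            (on_met, inaction),
            (LayerFlow("on_metformin", "inaction", q_met),),
            "on_metformin",
        )
    if kind == "ilc":
        return StrategySpec(
            kind,
            (on_ilc, inaction),
            (LayerFlow("on_ilc", "inaction", q_ilc),),
            "on_ilc",
        )
    if kind == "combination":
        return StrategySpec(
            kind,
            (on_both, met_only, inaction),
            (
                LayerFlow("on_both", "metformin_only", q_ilc),
                LayerFlow("metformin_only", "inaction", q_met),
            ),
            "on_both",
        )
    if kind == "titration":
        return StrategySpec(
            kind,
            (on_ilc, on_both, met_only, inaction),
            (
                LayerFlow("on_ilc", "on_both", q_ilc),
                LayerFlow("on_both", "metformin_only", q_ilc),
                LayerFlow("metformin_only", "inaction", q_met),
            ),
            "on_ilc",
        )
    raise ValueError(f"unknown strategy kind {kind!r}; choose from {STRATEGY_KINDS}")


def layer_effect_at(spec: StrategySpec, layer: str, month: int) -> float:
    """Annual T2D risk reduction active for a layer at a given model month."""
    if month < 1:
        raise ValueError("month must be >= 1")
    eff = spec.layer(layer).effect
    return 0.0 if eff is None else eff.at_month(month)
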