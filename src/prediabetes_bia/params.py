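"""Country parameter sets, packaged case studies, and synthetic countries.

A :class:`CountryParameters` bundles everything country-specific the model
needs: an age-banded adult population, the prediabetes/T2D prevalences, the
annual population growth rate (stored for provenance; the simulation follows
a closed cohort and never adds entrants), monthly intervention prices and
annual per-capita disease-state medical costs.

Three case studies (Poland, Saudi Arabia, Vietnam) ship as YAML fixtures
inside the package; :func:`generate_synthetic_country` produces structurally
identical parameter sets for testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

AGE_BAND_LABELS = ("20-29", "30-39", "40-49", "50-59", "60+")
FIXTURE_NAMES = ("poland", "saudi_arabia", "vietnam")


class ParameterError(ValueError):
    """A country parameter set violates an invariant."""


@dataclass(frozen=True)
class AgeBand:
    """One adult age band and its population headcount."""

    label: str
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ParameterError(f"band {self.label!r}: population must be >= 0")


@dataclass(frozen=True)
class InterventionCosts:
    """Monthly per-patient intervention prices (currency units/month)."""

    metformin_per_month: float
    ilc_per_month: float

    def __post_init__(self) -> None:
        if self.metformin_per_month < 0 or self.ilc_per_month < 0:
            raise ParameterError("intervention costs must be >= 0")


@dataclass(frozen=True)
class StateCosts:
    """Annual per-capita medical cost by health state (currency units/year).

    ``r_prediabetes`` and ``r_t2d`` are the relative cost ratios (disease-state
    per-capita spend over non-disease per-capita spend) used by the
    attributable-fraction derivation; death accrues zero cost.
    """

    normoglycemia_per_year: float
    prediabetes_per_year: float
    t2d_per_year: float
    r_prediabetes: float = 1.04
    r_t2d: float = 3.0

    def __post_init__(self) -> None:
        for name in ("normoglycemia_per_year", "prediabetes_per_year", "t2d_per_year"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def as_annual_vector(self) -> np.ndarray:
        """Costs in health-state order (normoglycemia, prediabetes, T2D, death)."""
        return np.array(
            [self.normoglycemia_per_year, self.prediabetes_per_year, self.t2d_per_year, 0.0]
        )


@dataclass(frozen=True)
class CountryParameters:
    name: str
    age_bands: tuple[AgeBand, ...]
    growth_rate: float
    prediabetes_prevalence: float
    t2d_prevalence: float
    intervention_costs: InterventionCosts
    state_costs: StateCosts
    #: headline survey prevalence where it differs from the effective rate
    #: implied by the published prevalent-cohort counts; informational only
    reported_prediabetes_prevalence: float | None = None

    def __post_init__(self) -> None:
        labels = [b.label for b in self.age_bands]
        if len(set(labels)) != len(labels):
            raise ParameterError("age band labels must be unique")
        for attr in ("prediabetes_prevalence", "t2d_prevalence"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{attr}={v} outside [0, 1]")

    @property
    def total_population(self) -> float:
        return float(sum(b.population for b in self.age_bands))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "growth_rate": self.growth_rate,
            "prediabetes_prevalence": self.prediabetes_prevalence,
            "t2d_prevalence": self.t2d_prevalence,
            "age_bands": [
                {"label": b.label, "population": b.population} for b in self.age_bands
            ],
            "intervention_costs": dataclasses.asdict(self.intervention_costs),
            "state_costs": dataclasses.asdict(self.state_costs),
        }
        if self.reported_prediabetes_prevalence is not None:
            d["reported_prediabetes_prevalence"] = self.reported_prediabetes_prevalence
        return d


def _country_from_dict(data: Mapping) -> CountryParameters:
    required = {
        "name",
        "age_bands",
        "growth_rate",
        "prediabetes_prevalence",
        "t2d_prevalence",
        "intervention_costs",
        "state_costs",
    }
    missing = required - set(data)
    if missing:
        raise ParameterError(f"country config missing fields: {sorted(missing)}")
    return CountryParameters(
        name=str(data["name"]),
        age_bands=tuple(
            AgeBand(label=str(b["label"]), population=float(b["population"]))
            for b in data["age_bands"]
        ),
        growth_rate=float(data["growth_rate"]),
        prediabetes_prevalence=float(data["prediabetes_prevalence"]),
        t2d_prevalence=float(data["t2d_prevalence"]),
        intervention_costs=InterventionCosts(**data["intervention_costs"]),
        state_costs=StateCosts(**data["state_costs"]),
        reported_prediabetes_prevalence=(
            float(data["reported_prediabetes_prevalence"])
            if data.get("reported_prediabetes_prevalence") is not None
            else None
        ),
    )


def load_country(name_or_path: str | Path) -> CountryParameters:
    """Load a packaged case study by name, or any country config by path.

    Parameters
    ----------
    name_or_path
        One of ``poland``, ``saudi_arabia``, ``vietnam``, or a path to a
        YAML/JSON file with the same keys as the packaged fixtures.
    """
    key = str(name_or_path)
    if key in FIXTURE_NAMES:
        text = (resources.files("prediabetes_bia") / "data" / f"{key}.yaml").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ParameterError(
                f"unknown fixture {key!r} (choose from {FIXTURE_NAMES}) and no such file"
            )
        text = path.read_text()
    return _country_from_dict(yaml.safe_load(text))


def save_country(country: CountryParameters, path: str | Path) -> None:
    """Write a country parameter set to YAML (round-trips with load_country)."""
    Path(path).write_text(yaml.safe_dump(country.to_dict(), sort_keys=False))


def prevalent_prediabetes_cohort(country: CountryParameters) -> float:
    """Size of the prevalent prediabetes cohort entering the model.

    Sum over age bands of population times the (uniform) prediabetes
    prevalence. Real-valued mass; round only for reporting.
    """
    return country.total_population * country.prediabetes_prevalence


def band_prevalent_counts(country: CountryParameters) -> dict[str, int]:
    """Per-band prevalent prediabetes counts rounded to whole persons."""
    return {
        b.label: int(round(b.population * country.prediabetes_prevalence))
        for b in country.age_bands
    }


@dataclass(frozen=True)
class SyntheticRanges:
    """Sampling bounds for :func:`generate_synthetic_country`.

    Defaults bracket the three case studies: effective prediabetes
    prevalence 5%-15%, band populations 1-20 million, normoglycemia
    per-capita annual costs spanning the Vietnam-Saudi range.
    """

    prediabetes_prevalence: tuple[float, float] = (0.05, 0.15)
    t2d_prevalence: tuple[float, float] = (0.04, 0.20)
    band_population: tuple[float, float] = (1e6, 2e7)
    growth_rate: tuple[float, float] = (-0.005, 0.015)
    metformin_per_month: tuple[float, float] = (4.0, 16.0)
    ilc_per_month: tuple[float, float] = (100.0, 300.0)
    normoglycemia_per_year: tuple[float, float] = (300.0, 1600.0)
    r_prediabetes: tuple[float, float] = (1.02, 1.10)
    r_t2d: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            lo, hi = getattr(self, f.name)
            if lo > hi:
                raise ParameterError(f"degenerate range for {f.name}: ({lo}, {hi})")


def generate_synthetic_country(
    seed: int, ranges: SyntheticRanges | None = None
) -> CountryParameters:
    """Draw a random but valid country parameter set.

    The disease-state cost vector is produced by the attributable-fraction
    derivation from a sampled normoglycemia per-capita cost and sampled
    relative cost ratios, so synthetic countries obey the same R-rate
    structure as the case studies. Deterministic in ``seed``.
    """
    from .costing import derive_state_costs  # local import avoids a cycle

    ranges = ranges or SyntheticRanges()
    rng = np.random.default_rng(seed)

    def draw(bounds: tuple[float, float]) -> float:
        lo, hi = bounds
        return float(rng.uniform(lo, hi))

    bands = tuple(
        AgeBand(label=lab, population=float(np.round(draw(ranges.band_population))))
        for lab in AGE_BAND_LABELS
    )
    state_costs = derive_state_costs(
        base_percap=draw(ranges.normoglycemia_per_year),
        r_prediabetes=draw(ranges.r_prediabetes),
        r_t2d=draw(ranges.r_t2d),
    )
    return CountryParameters(
        name=f"synthetic-{seed}",
        age_bands=bands,
        growth_rate=draw(ranges.growth_rate),
        prediabetes_prevalence=draw(ranges.prediabetes_prevalence),
        t2d_prevalence=draw(ranges.t2d_prevalence),
        intervention_costs=InterventionCosts(
            metformin_per_month=draw(ranges.metformin_per_month),
            ilc_per_month=draw(ranges.ilc_per_month),
        ),
        state_costs=state_costs,
    )
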