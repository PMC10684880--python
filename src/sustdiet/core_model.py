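"""Core domain model for composite-diet sustainability analysis.

A *composite diet* is a full daily diet described as mass shares of 14 food
groups over a fixed total daily mass (1800 g by default).  Diet scenarios
interpolate between three anchor diets — current, feasible (the per-group
midpoint of current and optimal) and optimal — by partially replacing
animal-based meats with legumes under three consumption models:

* M1 replaces red meat only,
* M2 replaces red and white meat,
* M3 replaces red, white and processed meat.

This module holds the shared value types and their validation; the scenario
construction, scoring and impact estimation live in sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import (
    NegativeShareError,
    SumNotOneError,
    UnknownGroupError,
)

#: The closed set of food-group labels a composite diet is described over.
FOOD_GROUPS: tuple[str, ...] = (
    "whole grains",
    "refined grains",
    "nuts",
    "legumes",
    "fruits",
    "vegetables",
    "fish/seafood",
    "red meat",
    "processed meat",
    "white meat",
    "dairy",
    "eggs",
    "added oils",
    "sugar-sweetened beverages",
)

#: Total daily diet mass in grams shared by every anchor and scenario.
DEFAULT_TOTAL_MASS_G: float = 1800.0

#: The three meat groups that substitution models may target.
MEAT_GROUPS: tuple[str, ...] = ("red meat", "white meat", "processed meat")

# Common synonyms seen in intake tables and risk-factor lists.
_ALIASES: dict[str, str] = {
    "fish": "fish/seafood",
    "seafood": "fish/seafood",
    "fish and seafood": "fish/seafood",
    "red meats": "red meat",
    "processed meats": "processed meat",
    "white meats": "white meat",
    "milk": "dairy",
    "milk/dairy": "dairy",
    "dairy products": "dairy",
    "beans/legumes": "legumes",
    "beans": "legumes",
    "pulses": "legumes",
    "nuts and seeds": "nuts",
    "nuts/seeds": "nuts",
    "seeds/nuts": "nuts",
    "ssb": "sugar-sweetened beverages",
    "sugar sweetened beverages": "sugar-sweetened beverages",
    "oils": "added oils",
    "egg": "eggs",
    "fruit": "fruits",
    "vegetable": "vegetables",
}

_CANONICAL = {g.lower(): g for g in FOOD_GROUPS}


def canonical_group(name: str) -> str:
    """Resolve ``name`` to its canonical food-group label (case-insensitive).

    Raises
    ------
    UnknownGroupError
        If the name is not one of the 14 groups or a known synonym.
    """
    key = str(name).strip().lower()
    if key in _CANONICAL:
        return _CANONICAL[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnknownGroupError(f"unknown food group: {name!r}")


@dataclass(frozen=True)
class FoodItem:
    """A representative food standing in for one food group.

    ``nutrients`` holds amounts per 100 g of the food (units carried by the
    source table's headers); ``impacts_per_racc`` holds the mean midpoint
    impact per reference amount customarily consumed (RACC).
    """

    id: str
    group: str
    kcal_per_100g: float
    nutrients: Mapping[str, float] = field(default_factory=dict)
    racc_g: float = 100.0
    impacts_per_racc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", canonical_group(self.group))
        if self.kcal_per_100g < 0:
            raise NegativeShareError(
                f"food {self.id!r}: kcal_per_100g must be >= 0",
                code="BAD_CONFIG",
            )
        if self.racc_g <= 0:
            raise NegativeShareError(
                f"food {self.id!r}: racc_g must be > 0", code="ZERO_RACC"
            )


@dataclass(frozen=True)
class DietComposition:
    """Mass shares of the 14 food groups over a fixed total daily mass.

    Shares are dimensionless fractions summing to one; groups omitted from
    ``shares`` are treated as zero.
    """

    shares: Mapping[str, float]
    total_mass_g: float = DEFAULT_TOTAL_MASS_G

    def __post_init__(self) -> None:
        canon = {canonical_group(g): float(v) for g, v in self.shares.items()}
        if len(canon) != len(self.shares):
            raise UnknownGroupError("duplicate food groups after canonicalisation")
        object.__setattr__(self, "shares", canon)

    def share(self, group: str) -> float:
        return self.shares.get(canonical_group(group), 0.0)


@dataclass(frozen=True)
class DietScenario:
    """A named point on the substitution ladder between anchors."""

    scenario_id: str
    composition: DietComposition
    anchor_flag: str = "intermediate"  # current | feasible | optimal | intermediate


_MODEL_TARGETS: dict[str, tuple[str, ...]] = {
    "M1": ("red meat",),
    "M2": ("red meat", "white meat"),
    "M3": ("red meat", "white meat", "processed meat"),
}


@dataclass(frozen=True)
class ConsumptionModel:
    """One of the three fixed meat-replacement models (M1/M2/M3)."""

    model_id: str
    targeted_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TARGETS:
            raise UnknownGroupError(
                f"unknown consumption model: {self.model_id!r}", code="BAD_CONFIG"
            )
        expected = _MODEL_TARGETS[self.model_id]
        targets = self.targeted_groups or expected
        targets = tuple(canonical_group(g) for g in targets)
        if set(targets) != set(expected):
            raise UnknownGroupError(
                f"{self.model_id} must target {expected}, got {targets}",
                code="BAD_CONFIG",
            )
        object.__setattr__(self, "targeted_groups", expected)


M1 = ConsumptionModel("M1")
M2 = ConsumptionModel("M2")
M3 = ConsumptionModel("M3")
ALL_MODELS: tuple[ConsumptionModel, ...] = (M1, M2, M3)


#: Canonical names of the 18 midpoint indicators, in reporting order.
INDICATORS: tuple[str, ...] = (
    "global warming short term",
    "global warming long term",
    "water use",
    "ionizing radiation",
    "mineral resources",
    "freshwater ecotoxicity",
    "ozone layer depletion",
    "fine particulate matter formation",
    "freshwater acidification",
    "fossil energy use",
    "marine eutrophication",
    "land occupation",
    "freshwater eutrophication",
    "terrestrial acidification",
    "human toxicity cancer",
    "human toxicity noncancer",
    "total ecosystem quality damage",
    "total human health damage",
)

#: Default unit strings per indicator (metadata only — never converted).
INDICATOR_UNITS: dict[str, str] = {
    "global warming short term": "kgCO2 eq",
    "global warming long term": "kgCO2 eq",
    "water use": "m3",
    "ionizing radiation": "Bq C-14 eq",
    "mineral resources": "kg deprived",
    "freshwater ecotoxicity": "CTU eq",
    "ozone layer depletion": "kg CFC-11 eq",
    "fine particulate matter formation": "kg PM2.5 eq",
    "freshwater acidification": "kg SO2 eq",
    "fossil energy use": "MJ",
    "marine eutrophication": "kg N eq",
    "land occupation": "ha-yr",
    "freshwater eutrophication": "kg PO4 eq",
    "terrestrial acidification": "kg SO2 eq",
    "human toxicity cancer": "CTUh",
    "human toxicity noncancer": "CTUh",
    "total ecosystem quality damage": "PDF.m2.yr",
    "total human health damage": "DALY",
}

PER_DIET_DAY = "per-diet-day"
PER_100_KCAL = "per-100-kcal"


@dataclass(frozen=True)
class ImpactVector:
    """Values of the 18 midpoint indicators on an explicit basis."""

    values: Mapping[str, float]
    basis: str = PER_DIET_DAY
    units: Mapping[str, str] = field(default_factory=lambda: dict(INDICATOR_UNITS))

    def __post_init__(self) -> None:
        missing = set(INDICATORS) - set(self.values)
        extra = set(self.values) - set(INDICATORS)
        if missing or extra:
            raise UnknownGroupError(
                f"impact vector must carry exactly the 18 indicators "
                f"(missing={sorted(missing)}, extra={sorted(extra)})",
                code="BAD_CONFIG",
            )
        if self.basis not in (PER_DIET_DAY, PER_100_KCAL):
            raise UnknownGroupError(
                f"unknown basis {self.basis!r}", code="BAD_CONFIG"
            )
        for k, v in self.values.items():
            if not (v >= 0) or v != v:
                raise NegativeShareError(
                    f"indicator {k!r} must be finite and >= 0, got {v}",
                    code="BAD_CONFIG",
                )

    def __getitem__(self, indicator: str) -> float:
        return self.values[indicator]


def validate_composition(c: DietComposition, *, atol: float = 1e-9) -> DietComposition:
    """Check a composition's invariants and return it unchanged.

    Raises
    ------
    NegativeShareError
        If any share is negative.
    SumNotOneError
        If shares do not sum to 1 within ``atol`` (the deviation is reported).
    """
    for g, v in c.shares.items():
        if v < 0:
            raise NegativeShareError(f"share of {g!r} is negative ({v})")
    total = sum(c.shares.values())
    if abs(total - 1.0) > atol:
        raise SumNotOneError(
            f"shares sum to {total:.12g}; deviation from 1 is {total - 1.0:+.3e}"
        )
    if c.total_mass_g <= 0:
        raise SumNotOneError(
            f"total_mass_g must be positive, got {c.total_mass_g}", code="BAD_CONFIG"
        )
    return c


def grams_of(c: DietComposition, group: str) -> float:
    """Daily intake of ``group`` in grams: share × total mass."""
    return c.share(group) * c.total_mass_g
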