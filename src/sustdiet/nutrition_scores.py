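"""Diet-quality scoring: HENI minutes and the adapted Food Compass Score.

Two complementary nutrient-profiling systems are implemented, both on a
100 kcal basis:

**HENI** (Health Nutritional Index) converts intakes of 15 dietary risk
factors (9 food groups + 6 nutrients, from Global Burden of Disease
epidemiology) into minutes of healthy life gained or lost per 100 kcal:

    HENI = -0.53 * sum_r factor_r * d_r

where ``factor_r`` is the DALY-scale risk factor and ``d_r`` the intake of
risk ``r`` per 100 kcal.  Beneficial components carry negative factors, so
they contribute positive minutes.

**Food Compass** maps each of 46 nutrient/ingredient attributes onto an
integer score through a cut-point ladder, groups them into 7 domains, and
aggregates as the mean of the six non-ingredient domain scores plus the
*sum* of the food-ingredient attribute scores.  The raw score is rescaled
to a 1–100 range by the affine map

    FCS = 100 - ((26.1 - raw) / 36.7) * 99.

The attribute cut-points shipped with this package are a documented,
non-authoritative placeholder configuration (monotone ladders with the
correct attribute and domain structure); authoritative cut-points can be
dropped in as data without code changes.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_model import DietComposition, canonical_group, grams_of
from .errors import (
    AllZeroError,
    EmptyDomainError,
    KeyMismatchError,
    MissingFoodError,
    NonMonotoneCutpointsError,
    UnitMismatchError,
    ZeroEnergyError,
)

logger = logging.getLogger(__name__)

#: Canonical names of the 15 dietary risk factors (9 food groups + 6 nutrients).
RISKS: tuple[str, ...] = (
    "calcium",
    "polyunsaturated fatty acids",
    "sodium",
    "trans fats",
    "whole grains",
    "nuts and seeds",
    "legumes",
    "vegetables",
    "fruits",
    "seafood",
    "processed meats",
    "red meats",
    "milk",
    "fiber",
    "sugar-sweetened beverages",
)

#: Food groups feeding the group-level risks (grams of group -> grams of risk).
GROUP_TO_RISK: dict[str, str] = {
    "whole grains": "whole grains",
    "nuts": "nuts and seeds",
    "legumes": "legumes",
    "vegetables": "vegetables",
    "fruits": "fruits",
    "fish/seafood": "seafood",
    "processed meat": "processed meats",
    "red meat": "red meats",
    "dairy": "milk",
    "sugar-sweetened beverages": "sugar-sweetened beverages",
}

#: Nutrient-level risks: the food-table column each reads from and the
#: factor converting the column's unit to grams (mineral columns are mg).
NUTRIENT_RISKS: dict[str, tuple[str, float]] = {
    "calcium": ("calcium", 1e-3),
    "polyunsaturated fatty acids": ("pufa", 1.0),
    "sodium": ("sodium", 1e-3),
    "trans fats": ("trans_fat", 1.0),
    "fiber": ("fiber", 1.0),
}

#: Conversion from DALY-scale risk burden to minutes (sign as published).
MINUTES_CONVERSION: float = -0.53


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient and ingredient amounts of a diet per 100 kcal."""

    amounts: Mapping[str, float]
    total_kcal_per_day: float
    basis_kcal: float = 100.0


@dataclass(frozen=True)
class RiskIntakeVector:
    """Intake of the 15 dietary risks per 100 kcal.

    All mass risks are carried in grams per 100 kcal (food groups, fiber,
    PUFA, trans fats, and sodium/calcium after mg-to-g conversion); the
    unit per risk can be overridden through ``units`` when a factor table
    declares a different intake scale.
    """

    d: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.d)
        if keys != set(RISKS):
            raise KeyMismatchError(
                f"risk vector must carry exactly the 15 risks "
                f"(missing={sorted(set(RISKS) - keys)}, "
                f"extra={sorted(keys - set(RISKS))})"
            )


@dataclass(frozen=True)
class HeniFactorTable:
    """DALY-scale factors per unit intake of each dietary risk."""

    factor: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)
    minutes_conversion: float = MINUTES_CONVERSION

    def __post_init__(self) -> None:
        keys = set(self.factor)
        if keys != set(RISKS):
            raise KeyMismatchError(
                f"factor table must carry exactly the 15 risks "
                f"(missing={sorted(set(RISKS) - keys)}, "
                f"extra={sorted(keys - set(RISKS))})"
            )
        largest = min(self.factor, key=lambda r: self.factor[r])
        if largest != "seafood":
            raise KeyMismatchError(
                "seafood must carry the largest-magnitude negative factor; "
                f"got {largest!r}",
                code="BAD_CONFIG",
            )


# ---------------------------------------------------------------------------
# Profile aggregation
# ---------------------------------------------------------------------------

_FOODS_REQUIRED = ("food_id", "group", "kcal_per_100g")
_META_COLS = {"food_id", "group", "kcal_per_100g", "racc_g"}


def aggregate_profile(
    c: DietComposition, foods: pd.DataFrame
) -> tuple[NutrientProfile, RiskIntakeVector]:
    """Aggregate a diet's nutrient profile and risk intakes per 100 kcal.

    ``foods`` is a food-composition table with columns ``food_id``,
    ``group``, ``kcal_per_100g`` and one column per nutrient attribute
    (amounts per 100 g).  If several foods represent one group, the group's
    mass is split equally among them.

    Per-day totals are computed as sum(grams x per-gram density) and then
    rescaled to a 100 kcal basis.  Group grams per 100 kcal enter the
    profile under the canonical group name (feeding the ingredient
    attributes of the Food Compass), and four derived nutrient ratios are
    appended when their denominators are positive.
    """
    missing = [col for col in _FOODS_REQUIRED if col not in foods.columns]
    if missing:
        raise MissingFoodError(f"food table lacks required columns {missing}")
    foods = foods.copy()
    foods["group"] = foods["group"].map(canonical_group)
    nutrient_cols = [col for col in foods.columns if col not in _META_COLS]

    kcal_day = 0.0
    nutrients_day = {col: 0.0 for col in nutrient_cols}
    # zero-share groups enter explicitly: 0 g is an observation, not a gap
    group_grams: dict[str, float] = {g: 0.0 for g in c.shares}
    for group, share in c.shares.items():
        grams = grams_of(c, group)
        if grams <= 0:
            continue
        rows = foods[foods["group"] == group]
        if rows.empty:
            raise MissingFoodError(f"no representative food for group {group!r}")
        group_grams[group] = group_grams.get(group, 0.0) + grams
        per_food = grams / len(rows)
        for _, row in rows.iterrows():
            kcal_day += per_food * float(row["kcal_per_100g"]) / 100.0
            for col in nutrient_cols:
                v = row[col]
                if pd.notna(v):
                    nutrients_day[col] += per_food * float(v) / 100.0
    if kcal_day <= 0:
        raise ZeroEnergyError(
            "diet provides no energy", code="ZERO_ENERGY_DIET"
        )

    scale = 100.0 / kcal_day
    amounts = {col: v * scale for col, v in nutrients_day.items()}
    amounts.update({g: grams * scale for g, grams in group_grams.items()})

    def ratio(num: str, den: str, name: str) -> None:
        if amounts.get(den, 0.0) > 0:
            amounts[name] = amounts.get(num, 0.0) / amounts[den]

    ratio("fiber", "carbohydrate", "fiber_carb_ratio")
    ratio("potassium", "sodium", "potassium_sodium_ratio")
    if amounts.get("sat_fat", 0.0) > 0:
        amounts["unsat_sat_fat_ratio"] = (
            amounts.get("mufa", 0.0) + amounts.get("pufa", 0.0)
        ) / amounts["sat_fat"]
    ratio("sugar", "carbohydrate", "sugar_carb_ratio")

    d = {risk: 0.0 for risk in RISKS}
    for group, risk in GROUP_TO_RISK.items():
        d[risk] = amounts.get(group, 0.0)
    for risk, (col, to_grams) in NUTRIENT_RISKS.items():
        d[risk] = amounts.get(col, 0.0) * to_grams

    profile = NutrientProfile(amounts=amounts, total_kcal_per_day=kcal_day)
    return profile, RiskIntakeVector(d=d)


# ---------------------------------------------------------------------------
# HENI
# ---------------------------------------------------------------------------


def heni_score(d: RiskIntakeVector, t: HeniFactorTable) -> float:
    """HENI minutes per 100 kcal: ``-0.53 * sum_r factor_r * d_r``."""
    if set(d.d) != set(t.factor):
        raise KeyMismatchError("risk vector and factor table keys differ")
    if t.units and d.units:
        clashes = {
            r: (d.units[r], t.units[r])
            for r in t.units
            if r in d.units and d.units[r] != t.units[r]
        }
        if clashes:
            raise UnitMismatchError(
                f"risk vector and factor table disagree on units: {clashes}"
            )
    return t.minutes_conversion * sum(t.factor[r] * d.d[r] for r in t.factor)


def risk_contributions(d: RiskIntakeVector, t: HeniFactorTable) -> dict[str, float]:
    """Percent contribution of each risk to |HENI|, summing to 100."""
    products = {r: abs(t.factor[r] * d.d[r]) for r in t.factor}
    total = sum(products.values())
    if total <= 0:
        raise AllZeroError("all risk contributions are zero")
    return {r: 100.0 * v / total for r, v in products.items()}


# ---------------------------------------------------------------------------
# Food Compass
# ---------------------------------------------------------------------------

DOMAINS: tuple[str, ...] = (
    "nutrient ratios",
    "vitamins",
    "minerals",
    "food ingredients",
    "additives",
    "specific lipids",
    "protein & fiber",
)
INGREDIENT_DOMAIN = "food ingredients"

#: Eq-style scaling constants of the 1-100 rescaling.
SCALING_UPPER = 26.1
SCALING_SPAN = 36.7
SCALING_RANGE = 99.0


@dataclass(frozen=True)
class FcsAttribute:
    """One scored attribute: a monotone cut-point ladder.

    ``thresholds`` are ascending attribute values; ``scores`` has one more
    entry than ``thresholds`` and is non-decreasing for beneficial
    attributes and non-increasing for harmful ones.  A value exactly on a
    cut-point takes the score of the healthier side.
    """

    name: str
    domain: str
    direction: str  # beneficial | harmful
    thresholds: tuple[float, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if self.direction not in ("beneficial", "harmful"):
            raise NonMonotoneCutpointsError(
                f"{self.name}: direction must be beneficial|harmful",
                code="BAD_CONFIG",
            )
        if len(self.scores) != len(self.thresholds) + 1:
            raise NonMonotoneCutpointsError(
                f"{self.name}: need len(scores) == len(thresholds) + 1"
            )
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise NonMonotoneCutpointsError(
                f"{self.name}: thresholds must be strictly ascending"
            )
        pairs = zip(self.scores, self.scores[1:])
        ok = (
            all(b >= a for a, b in pairs)
            if self.direction == "beneficial"
            else all(b <= a for a, b in pairs)
        )
        if not ok:
            raise NonMonotoneCutpointsError(
                f"{self.name}: scores must be monotone along the "
                f"{self.direction} direction"
            )

    def score(self, value: float) -> float:
        # ties go to the healthier side: the upper rung for beneficial
        # attributes, the lower rung for harmful ones
        if self.direction == "beneficial":
            return self.scores[bisect_right(self.thresholds, value)]
        return self.scores[bisect_left(self.thresholds, value)]


@dataclass(frozen=True)
class FcsConfig:
    """Attribute ladders, domain membership and scaling constants."""

    attributes: tuple[FcsAttribute, ...]
    domains: tuple[str, ...] = DOMAINS
    scaling_upper: float = SCALING_UPPER
    scaling_span: float = SCALING_SPAN
    scaling_range: float = SCALING_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "domains", tuple(self.domains))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise NonMonotoneCutpointsError(
                "duplicate attribute names", code="BAD_CONFIG"
            )
        for a in self.attributes:
            if a.domain not in self.domains:
                raise EmptyDomainError(
                    f"attribute {a.name!r} assigned to unknown domain {a.domain!r}",
                    code="BAD_CONFIG",
                )

    def validate_full(self) -> "FcsConfig":
        """Enforce the full 46-attribute / 7-domain adapted structure."""
        if len(self.attributes) != 46:
            raise EmptyDomainError(
                f"adapted Food Compass needs 46 attributes, got "
                f"{len(self.attributes)}",
                code="BAD_CONFIG",
            )
        if tuple(self.domains) != DOMAINS:
            raise EmptyDomainError(
                "adapted Food Compass needs exactly the 7 canonical domains",
                code="BAD_CONFIG",
            )
        names = {a.name for a in self.attributes}
        for excluded in ("iodine", "trans_fat_attr", "mcfa", "flavonoids", "carotenoids"):
            if excluded in names:
                raise EmptyDomainError(
                    f"excluded attribute {excluded!r} present", code="BAD_CONFIG"
                )
        if not {"red meat", "processed meat"} <= names:
            raise EmptyDomainError(
                "red and processed meats must be separate attributes",
                code="BAD_CONFIG",
            )
        for domain in self.domains:
            if not any(a.domain == domain for a in self.attributes):
                raise EmptyDomainError(f"domain {domain!r} has no attributes")
        return self


def score_attributes(p: NutrientProfile, cfg: FcsConfig) -> dict[str, float]:
    """Map each attribute's per-100-kcal value to its ladder score.

    Attributes absent from the profile score 0 (logged), mirroring the
    exclusion of unavailable data rather than failing the whole diet.
    """
    out: dict[str, float] = {}
    for attr in cfg.attributes:
        if attr.name in p.amounts:
            out[attr.name] = attr.score(float(p.amounts[attr.name]))
        else:
            logger.debug("attribute %r missing from profile; scored 0", attr.name)
            out[attr.name] = 0.0
    return out


def raw_fcs(
    attribute_scores: Mapping[str, float], cfg: FcsConfig
) -> tuple[float, dict[str, float]]:
    """Aggregate attribute scores into the raw (unscaled) Food Compass score.

    Domain score = mean of the domain's attribute scores.  The raw score is
    the mean of the six non-ingredient domain scores plus the *sum* of the
    food-ingredient attribute scores.
    """
    by_domain: dict[str, list[float]] = {d: [] for d in cfg.domains}
    for attr in cfg.attributes:
        by_domain[attr.domain].append(float(attribute_scores.get(attr.name, 0.0)))
    domain_scores: dict[str, float] = {}
    for domain, scores in by_domain.items():
        if not scores:
            raise EmptyDomainError(f"domain {domain!r} has no attributes")
        domain_scores[domain] = sum(scores) / len(scores)
    non_ingredient = [d for d in cfg.domains if d != INGREDIENT_DOMAIN]
    mean_domain = sum(domain_scores[d] for d in non_ingredient) / len(non_ingredient)
    ingredient_sum = sum(by_domain.get(INGREDIENT_DOMAIN, []))
    return mean_domain + ingredient_sum, domain_scores


def scale_fcs(raw: float, cfg: FcsConfig | None = None) -> float:
    """Affine 1-100 rescaling of the raw score (no clamping).

    ``raw = 26.1`` maps to 100 and ``raw = -10.6`` maps to 1 under the
    default constants; out-of-range raw scores yield out-of-range scaled
    scores and emit a warning.
    """
    upper = cfg.scaling_upper if cfg else SCALING_UPPER
    span = cfg.scaling_span if cfg else SCALING_SPAN
    rng = cfg.scaling_range if cfg else SCALING_RANGE
    scaled = 100.0 - ((upper - raw) / span) * rng
    if not (100.0 - rng - 1e-9 <= scaled <= 100.0 + 1e-9):
        warnings.warn(
            f"raw score {raw:.4g} scales to {scaled:.4g}, outside "
            f"[{100.0 - rng:g}, 100]",
            stacklevel=2,
        )
    return scaled


@dataclass(frozen=True)
class ScoreCard:
    """Joint nutrition scores of one diet."""

    raw_fcs: float
    scaled_fcs: float
    domain_scores: Mapping[str, float]
    heni_minutes: float
    contributions: Mapping[str, float] | None = None


def score_diet(
    c: DietComposition,
    foods: pd.DataFrame,
    heni_table: HeniFactorTable,
    fcs_config: FcsConfig,
) -> ScoreCard:
    """Full nutrition scoring of one diet composition."""
    profile, risks = aggregate_profile(c, foods)
    attr_scores = score_attributes(profile, fcs_config)
    raw, domain_scores = raw_fcs(attr_scores, fcs_config)
    scaled = scale_fcs(raw, fcs_config)
    heni = heni_score(risks, heni_table)
    try:
        contributions = risk_contributions(risks, heni_table)
    except AllZeroError:
        contributions = None
    return ScoreCard(
        raw_fcs=raw,
        scaled_fcs=scaled,
        domain_scores=domain_scores,
        heni_minutes=heni,
        contributions=contributions,
    )
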