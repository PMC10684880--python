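"""Synthetic inputs and packaged fixtures.

Two kinds of data feed the pipeline's tests and demonstrations:

* **Packaged fixtures** — the published 24-scenario score table, the
  15-row dietary-risk factor table, and the scenario compositions printed
  for the substitution-active groups.  These are verbatim data shipped as
  checksummed CSVs.

* **Synthetic worlds** — seeded generators for a food-composition table,
  an impact-factor table and an anchor set with the statistical structure
  the analysis assumes: a 14-group daily diet of fixed 1800 g mass, a
  feasible anchor at the per-group midpoint of current and optimal,
  animal-meat global-warming factors several-fold larger per gram than
  legume factors, and nutrient densities under which meat-heavy diets
  score lower on beneficial attributes.  Synthetic worlds exercise the
  pipeline's structure; they do not attempt to reproduce the published
  absolute scores (the shipped Food Compass cut-points are placeholders).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    FOOD_GROUPS,
    INDICATOR_UNITS,
    INDICATORS,
    DEFAULT_TOTAL_MASS_G,
    DietComposition,
    validate_composition,
)
from .environmental_impacts import ImpactFactorTable
from .errors import BadConfigError, ChecksumMismatchError
from .nutrition_scores import HeniFactorTable
from .scenario_builder import AnchorSet, StepSchedule, complete_overrides

DEFAULT_SEED = 20231128

# ---------------------------------------------------------------------------
# Anchor diets (percent of total daily mass)
# ---------------------------------------------------------------------------

#: Current-diet anchor shares in percent.  The four substitution-active
#: groups carry the published values; the remaining ten groups are the
#: package's own realistic allocation of the residual mass (meat-, refined-
#: grain- and SSB-heavy, low in whole grains, nuts, legumes and fish).
CURRENT_PERCENT: dict[str, float] = {
    "whole grains": 5.56,
    "refined grains": 16.67,
    "nuts": 1.39,
    "legumes": 0.00,
    "fruits": 11.11,
    "vegetables": 13.89,
    "fish/seafood": 1.67,
    "red meat": 5.56,
    "processed meat": 2.78,
    "white meat": 4.17,
    "dairy": 16.67,
    "eggs": 2.78,
    "added oils": 3.33,
    "sugar-sweetened beverages": 14.42,
}

#: Optimal-diet anchor shares in percent: published values for the active
#: groups, sugar-sweetened beverages eliminated, plant groups raised.
OPTIMAL_PERCENT: dict[str, float] = {
    "whole grains": 12.50,
    "refined grains": 8.33,
    "nuts": 5.56,
    "legumes": 11.11,
    "fruits": 16.67,
    "vegetables": 22.21,
    "fish/seafood": 5.56,
    "red meat": 0.00,
    "processed meat": 0.00,
    "white meat": 2.78,
    "dairy": 11.11,
    "eggs": 1.39,
    "added oils": 2.78,
    "sugar-sweetened beverages": 0.00,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic world.

    ``meat_to_legume_ghg_ratio`` is the minimum ratio of any targeted
    meat's per-gram global-warming factor to the legume factor; the default
    of 5 reflects the several-fold per-gram emission gap between animal
    meats and pulses.  ``noise_cv`` is the coefficient of variation of the
    mean-preserving lognormal jitter applied to densities and factors.
    """

    seed: int = DEFAULT_SEED
    n_foods_per_group: int = 1
    meat_to_legume_ghg_ratio: float = 5.0
    calorie_density_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.meat_to_legume_ghg_ratio <= 1:
            raise BadConfigError("meat_to_legume_ghg_ratio must exceed 1")
        if self.n_foods_per_group < 1:
            raise BadConfigError("n_foods_per_group must be >= 1")
        if not (0 <= self.noise_cv < 1):
            raise BadConfigError("noise_cv must be in [0, 1)")
        for g, (lo, hi) in self.calorie_density_ranges.items():
            if not (0 < lo <= hi):
                raise BadConfigError(
                    f"calorie range for {g!r} must satisfy 0 < lo <= hi"
                )


# Per-100 g macronutrient templates (uncooked representative foods).
_MACROS: dict[str, dict[str, float]] = {
    # group: kcal, protein, fat, sat_fat, pufa, carbohydrate, sugar, fiber
    "whole grains": dict(kcal=340, protein=12, fat=2.5, sat_fat=0.5, pufa=1.0, carbohydrate=72, sugar=1.0, fiber=11),
    "refined grains": dict(kcal=360, protein=10, fat=1.5, sat_fat=0.3, pufa=0.6, carbohydrate=76, sugar=0.5, fiber=3),
    "nuts": dict(kcal=600, protein=20, fat=54, sat_fat=6, pufa=20, carbohydrate=16, sugar=4, fiber=8),
    "legumes": dict(kcal=340, protein=22, fat=1.5, sat_fat=0.3, pufa=0.7, carbohydrate=60, sugar=3, fiber=15),
    "fruits": dict(kcal=55, protein=0.8, fat=0.3, sat_fat=0.05, pufa=0.1, carbohydrate=14, sugar=10, fiber=2.2),
    "vegetables": dict(kcal=30, protein=2, fat=0.3, sat_fat=0.05, pufa=0.1, carbohydrate=5.5, sugar=2.5, fiber=2.5),
    "fish/seafood": dict(kcal=120, protein=20, fat=4.5, sat_fat=1.0, pufa=1.5, carbohydrate=0, sugar=0, fiber=0),
    "red meat": dict(kcal=250, protein=17, fat=20, sat_fat=8, pufa=0.7, carbohydrate=0, sugar=0, fiber=0),
    "processed meat": dict(kcal=300, protein=14, fat=27, sat_fat=10, pufa=2.5, carbohydrate=2, sugar=1, fiber=0),
    "white meat": dict(kcal=165, protein=20, fat=9, sat_fat=2.5, pufa=1.9, carbohydrate=0, sugar=0, fiber=0),
    "dairy": dict(kcal=62, protein=3.3, fat=3.3, sat_fat=2.0, pufa=0.2, carbohydrate=4.8, sugar=4.8, fiber=0),
    "eggs": dict(kcal=150, protein=12.5, fat=10, sat_fat=3.3, pufa=1.9, carbohydrate=1, sugar=0.5, fiber=0),
    "added oils": dict(kcal=880, protein=0, fat=100, sat_fat=14, pufa=30, carbohydrate=0, sugar=0, fiber=0),
    "sugar-sweetened beverages": dict(kcal=40, protein=0, fat=0, sat_fat=0, pufa=0, carbohydrate=10.5, sugar=10.5, fiber=0),
}

_PLANT_GROUPS = {
    "whole grains", "refined grains", "nuts", "legumes", "fruits",
    "vegetables", "added oils", "sugar-sweetened beverages",
}

# Micronutrient archetypes per 100 g (plant vs animal matrices), scaled per
# group below.  Units: vitamins in conventional label units, minerals mg
# except selenium (ug), vitamin_a/folate/vitamin_k (ug).
_PLANT_MICRO = dict(
    vitamin_a=50, vitamin_c=20, vitamin_d=0.0, vitamin_e=1.5, vitamin_k=40,
    thiamin=0.15, riboflavin=0.10, niacin=1.5, vitamin_b6=0.15, folate=60,
    vitamin_b12=0.0, choline=20, calcium=40, iron=1.5, magnesium=40,
    phosphorus=80, potassium=300, sodium=10, zinc=0.8, copper=0.15,
    selenium=2, manganese=0.5, cholesterol=0, ala=0.05, epa=0, dha=0,
    trans_fat=0,
)
_ANIMAL_MICRO = dict(
    vitamin_a=30, vitamin_c=0.5, vitamin_d=0.8, vitamin_e=0.4, vitamin_k=2,
    thiamin=0.08, riboflavin=0.20, niacin=4.0, vitamin_b6=0.30, folate=8,
    vitamin_b12=1.5, choline=70, calcium=15, iron=1.8, magnesium=20,
    phosphorus=180, potassium=280, sodium=70, zinc=3.0, copper=0.08,
    selenium=15, manganese=0.03, cholesterol=70, ala=0.02, epa=0, dha=0,
    trans_fat=0,
)

_MICRO_MULT = {
    "whole grains": 1.0, "refined grains": 0.4, "nuts": 1.0, "legumes": 1.2,
    "fruits": 1.0, "vegetables": 1.5, "added oils": 0.05,
    "sugar-sweetened beverages": 0.02, "fish/seafood": 1.2, "red meat": 1.0,
    "processed meat": 0.8, "white meat": 1.0, "dairy": 1.0, "eggs": 1.2,
}

# Group-specific micronutrient overrides (per 100 g).
_MICRO_OVERRIDES: dict[str, dict[str, float]] = {
    "dairy": dict(calcium=120, vitamin_d=1.0),
    "processed meat": dict(sodium=900, trans_fat=0.3),
    "eggs": dict(choline=294, cholesterol=370, vitamin_d=2.0),
    "fish/seafood": dict(epa=0.3, dha=0.5, vitamin_d=5.0, cholesterol=55),
    "nuts": dict(ala=3.0, vitamin_e=9.0),
    "added oils": dict(ala=7.0, vitamin_e=14.0),
    "white meat": dict(cholesterol=75),
    "red meat": dict(cholesterol=70, iron=2.6, vitamin_b12=2.5),
}

#: Reference amount customarily consumed per group (g).
_RACC_G = {
    "whole grains": 55, "refined grains": 55, "nuts": 30, "legumes": 35,
    "fruits": 140, "vegetables": 85, "fish/seafood": 85, "red meat": 85,
    "processed meat": 55, "white meat": 85, "dairy": 240, "eggs": 50,
    "added oils": 15, "sugar-sweetened beverages": 360,
}

#: Base global-warming (short term) factor per gram, kgCO2 eq/g.
_GHG_PER_G = {
    "whole grains": 0.0012, "refined grains": 0.0011, "nuts": 0.0016,
    "legumes": 0.0009, "fruits": 0.0009, "vegetables": 0.0010,
    "fish/seafood": 0.0040, "red meat": 0.0120, "processed meat": 0.0100,
    "white meat": 0.0050, "dairy": 0.0025, "eggs": 0.0035,
    "added oils": 0.0030, "sugar-sweetened beverages": 0.0007,
}

# Indicator scales relative to the group's per-gram GHG factor, plus a
# multiplier applied to plant groups only (water use and freshwater
# eutrophication lean plant-heavy, reproducing the published nuance that
# the plant-rich optimal diet peaks on those two indicators).
_IND_SCALE: dict[str, tuple[float, float]] = {
    "global warming short term": (1.0, 1.0),
    "global warming long term": (0.8, 1.0),
    "water use": (0.010, 3.0),
    "ionizing radiation": (10.0, 1.2),
    "mineral resources": (0.30, 1.0),
    "freshwater ecotoxicity": (5.0, 1.0),
    "ozone layer depletion": (1e-6, 1.0),
    "fine particulate matter formation": (0.001, 1.0),
    "freshwater acidification": (0.010, 1.0),
    "fossil energy use": (7.0, 1.1),
    "marine eutrophication": (0.005, 1.0),
    "land occupation": (0.75, 1.0),
    "freshwater eutrophication": (0.005, 3.5),
    "terrestrial acidification": (0.010, 1.0),
    "human toxicity cancer": (1e-7, 1.0),
    "human toxicity noncancer": (2e-7, 1.0),
    "total ecosystem quality damage": (1.3, 1.0),
    "total human health damage": (1e-6, 1.0),
}

_MEATS = ("red meat", "processed meat", "white meat")


def _jitter(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-preserving lognormal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def generate_foods(
    cfg: SynthConfig | None = None,
) -> tuple[pd.DataFrame, ImpactFactorTable, dict[str, dict[str, float]]]:
    """Generate a food-composition table, impact-factor table and food map.

    Returns ``(foods, impact_table, food_map)`` where ``foods`` has one row
    per representative food (columns: food_id, group, kcal_per_100g,
    racc_g, nutrient columns per 100 g), ``impact_table`` carries per-RACC
    mean impacts for the 18 indicators, and ``food_map`` assigns each group
    its foods with equal mass weights.  Deterministic under a fixed seed;
    every targeted meat's per-gram global-warming factor is at least
    ``meat_to_legume_ghg_ratio`` times the legume factor.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    records: list[dict] = []
    rows: dict[str, tuple[float, dict[str, float]]] = {}
    food_map: dict[str, dict[str, float]] = {}

    # legume GHG factor first: the floor for meat factors
    legume_ghg = _GHG_PER_G["legumes"] * float(_jitter(rng, cfg.noise_cv))

    for group in FOOD_GROUPS:
        macros = _MACROS[group]
        micro_base = _PLANT_MICRO if group in _PLANT_GROUPS else _ANIMAL_MICRO
        mult = _MICRO_MULT[group]
        overrides = _MICRO_OVERRIDES.get(group, {})
        lo, hi = cfg.calorie_density_ranges.get(
            group, (macros["kcal"] * 0.9, macros["kcal"] * 1.1)
        )
        food_map[group] = {}
        for i in range(cfg.n_foods_per_group):
            food_id = f"{group}_{i + 1}" if cfg.n_foods_per_group > 1 else group
            kcal = float(rng.uniform(lo, hi))
            rec: dict = {
                "food_id": food_id,
                "group": group,
                "kcal_per_100g": round(kcal, 2),
                "racc_g": float(_RACC_G[group]),
            }
            for key, v in macros.items():
                if key == "kcal":
                    continue
                rec[key] = round(v * float(_jitter(rng, cfg.noise_cv)), 4)
            # monounsaturated fat closes the fat balance
            rec["mufa"] = round(max(rec["fat"] - rec["sat_fat"] - rec["pufa"], 0.0), 4)
            for key, v in micro_base.items():
                base = overrides.get(key, v * mult)
                rec[key] = round(base * float(_jitter(rng, cfg.noise_cv)), 4)
            records.append(rec)

            if group == "legumes" and i == 0:
                ghg = legume_ghg
            else:
                ghg = _GHG_PER_G[group] * float(_jitter(rng, cfg.noise_cv))
                if group in _MEATS:
                    ghg = max(ghg, cfg.meat_to_legume_ghg_ratio * legume_ghg)
            plant = group in _PLANT_GROUPS
            impacts: dict[str, float] = {}
            for ind in INDICATORS:
                scale, plant_mult = _IND_SCALE[ind]
                per_g = scale * ghg * (plant_mult if plant else 1.0)
                if ind not in (
                    "global warming short term",
                    "global warming long term",
                ):
                    per_g *= float(_jitter(rng, cfg.noise_cv))
                impacts[ind] = per_g * _RACC_G[group]
            rows[food_id] = (float(_RACC_G[group]), impacts)
            food_map[group][food_id] = 1.0

    foods = pd.DataFrame.from_records(records)
    table = ImpactFactorTable(rows=rows, units=dict(INDICATOR_UNITS))
    return foods, table, food_map


def generate_anchors(cfg: SynthConfig | None = None) -> AnchorSet:
    """The current / feasible / optimal anchor compositions.

    The current and optimal anchors carry the published shares of the
    substitution-active groups; the feasible anchor is the per-group
    arithmetic midpoint.  Anchors are fixed study conditions, not sampled.
    """
    del cfg  # anchors carry no randomness; signature kept uniform
    current = {g: v / 100.0 for g, v in CURRENT_PERCENT.items()}
    optimal = {g: v / 100.0 for g, v in OPTIMAL_PERCENT.items()}
    feasible = {g: (current[g] + optimal[g]) / 2.0 for g in current}
    make = lambda shares: validate_composition(
        DietComposition(shares, total_mass_g=DEFAULT_TOTAL_MASS_G), atol=1e-6
    )
    return AnchorSet(
        current=make(current), feasible=make(feasible), optimal=make(optimal)
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSet:
    """The packaged published tables."""

    table1: pd.DataFrame
    table2: HeniFactorTable
    printed_compositions: dict[str, dict[str, float]]
    checksums: dict[str, str]


def _data_bytes(name: str) -> bytes:
    return resources.files("sustdiet.data").joinpath(name).read_bytes()


def load_fixtures(verify: bool = True) -> FixtureSet:
    """Load and checksum-verify the packaged fixture tables.

    ``printed_compositions`` maps scenario ids to fractional shares of the
    substitution-active groups (the CSV stores percent of total mass).
    """
    import io

    expected = json.loads(_data_bytes("checksums.json"))
    blobs: dict[str, bytes] = {}
    for name in ("table1_scores.csv", "heni_factors.csv", "printed_compositions.csv"):
        blob = _data_bytes(name)
        if verify:
            digest = hashlib.sha256(blob).hexdigest()
            if digest != expected[name]:
                raise ChecksumMismatchError(
                    f"fixture {name}: sha256 {digest} != recorded {expected[name]}"
                )
        blobs[name] = blob

    table1 = pd.read_csv(io.BytesIO(blobs["table1_scores.csv"]))
    t2 = pd.read_csv(io.BytesIO(blobs["heni_factors.csv"]))
    table2 = HeniFactorTable(
        factor=dict(zip(t2["risk"], t2["factor"].astype(float))),
        units=dict(zip(t2["risk"], t2["unit"])),
    )
    comp = pd.read_csv(io.BytesIO(blobs["printed_compositions.csv"]))
    printed: dict[str, dict[str, float]] = {}
    for sid, sub in comp.groupby("scenario_id"):
        printed[str(sid)] = {
            str(r["group"]): float(r["percent_of_mass"]) / 100.0
            for _, r in sub.iterrows()
        }
    return FixtureSet(
        table1=table1,
        table2=table2,
        printed_compositions=printed,
        checksums=dict(expected),
    )


def default_schedule(
    n_intermediate_low: int = 3, n_intermediate_high: int = 4
) -> StepSchedule:
    """Override-mode schedule completed from the printed compositions.

    Printed scenarios are taken verbatim; the unprinted intermediates are
    filled by piecewise-linear interpolation between the printed knots (see
    :func:`sustdiet.scenario_builder.complete_overrides`).
    """
    fixtures = load_fixtures()
    overrides, _ = complete_overrides(
        fixtures.printed_compositions,
        n_intermediate_low=n_intermediate_low,
        n_intermediate_high=n_intermediate_high,
    )
    return StepSchedule(
        mode="override",
        overrides=overrides,
        n_intermediate_low=n_intermediate_low,
        n_intermediate_high=n_intermediate_high,
    )
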