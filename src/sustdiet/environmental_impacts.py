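"""Midpoint environmental impact estimation for composite diets.

Each representative food carries a mean impact per reference amount
customarily consumed (RACC) for 18 midpoint indicators.  Dividing by the
RACC mass yields a per-gram factor; multiplying by the grams of the
ingredient in the diet and summing over ingredients gives the diet's
per-day impact, which is also reported per 100 kcal.  Impacts are additive
means: no life-cycle inventory modelling or uncertainty propagation is
done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core_model import (
    INDICATOR_UNITS,
    INDICATORS,
    PER_100_KCAL,
    PER_DIET_DAY,
    DietComposition,
    ImpactVector,
    canonical_group,
    grams_of,
)
from .errors import (
    MissingFactorError,
    ZeroBaselineError,
    ZeroEnergyError,
    ZeroRaccError,
)


@dataclass(frozen=True)
class ImpactFactorTable:
    """Per-food mean midpoint impacts per RACC, with the RACC mass.

    ``rows`` maps a food id to ``(racc_g, {indicator: mean impact per
    RACC})``; ``units`` carries the indicator unit strings verbatim.
    """

    rows: Mapping[str, tuple[float, Mapping[str, float]]]
    units: Mapping[str, str] = field(default_factory=lambda: dict(INDICATOR_UNITS))

    def __post_init__(self) -> None:
        for food_id, (racc_g, impacts) in self.rows.items():
            if racc_g <= 0:
                raise ZeroRaccError(f"food {food_id!r}: racc_g must be > 0")
            missing = set(INDICATORS) - set(impacts)
            if missing:
                raise MissingFactorError(
                    f"food {food_id!r} lacks indicators {sorted(missing)}"
                )
            for ind, v in impacts.items():
                if not (v >= 0) or v != v:
                    raise MissingFactorError(
                        f"food {food_id!r}, indicator {ind!r}: impact must be "
                        f"finite and >= 0, got {v}"
                    )

    def per_gram(self, food_id: str, indicator: str) -> float:
        racc_g, impacts = self.rows[food_id]
        return per_gram_factor(impacts[indicator], racc_g)


def per_gram_factor(mean_impact: float, racc_g: float) -> float:
    """Impact per gram: mean impact per RACC divided by the RACC mass."""
    if racc_g <= 0:
        raise ZeroRaccError(f"racc_g must be > 0, got {racc_g}")
    return mean_impact / racc_g


def diet_impacts(
    c: DietComposition,
    t: ImpactFactorTable,
    food_map: Mapping[str, str | Mapping[str, float]],
) -> ImpactVector:
    """Per-diet-day impact vector of a composition.

    ``food_map`` assigns each food group either a single representative
    food id or a mapping of food ids to mass weights (weights are
    normalised, allowing multi-food splits within a group).
    """
    canon_map = {canonical_group(g): spec for g, spec in food_map.items()}
    totals = {ind: 0.0 for ind in INDICATORS}
    for group in c.shares:
        grams = grams_of(c, group)
        if grams <= 0:
            continue
        if group not in canon_map:
            raise MissingFactorError(f"no food mapped for group {group!r}")
        spec = canon_map[group]
        weights: dict[str, float]
        if isinstance(spec, str):
            weights = {spec: 1.0}
        else:
            wsum = sum(spec.values())
            if wsum <= 0:
                raise MissingFactorError(
                    f"group {group!r}: food weights must sum to > 0"
                )
            weights = {fid: w / wsum for fid, w in spec.items()}
        for food_id, w in weights.items():
            if food_id not in t.rows:
                raise MissingFactorError(
                    f"food {food_id!r} (group {group!r}) missing from factor table"
                )
            for ind in INDICATORS:
                totals[ind] += t.per_gram(food_id, ind) * grams * w
    return ImpactVector(values=totals, basis=PER_DIET_DAY, units=dict(t.units))


def normalize_per_100kcal(v: ImpactVector, total_kcal: float) -> ImpactVector:
    """Rescale a per-day impact vector to a 100 kcal basis."""
    if total_kcal <= 0:
        raise ZeroEnergyError(f"total_kcal must be > 0, got {total_kcal}")
    scale = 100.0 / total_kcal
    return ImpactVector(
        values={k: val * scale for k, val in v.values.items()},
        basis=PER_100_KCAL,
        units=dict(v.units),
    )


def percent_change(baseline: float, alternative: float) -> float:
    """Percent reduction relative to baseline (positive = reduction)."""
    if baseline == 0:
        raise ZeroBaselineError("baseline must be nonzero")
    return (baseline - alternative) / baseline * 100.0
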