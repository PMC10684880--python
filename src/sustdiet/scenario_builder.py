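"""Construction of the 24 meat-to-legume substitution diet scenarios.

The scenario design interpolates between three anchor diets — current (S1),
feasible (S5, the per-group midpoint of current and optimal) and optimal
(S10) — under three consumption models that target red meat (M1), red and
white meat (M2), or red, white and processed meat (M3).  Each model adds
seven intermediate scenarios (S2–S4 between current and feasible, S6–S9
between feasible and optimal), so the full design holds 3 shared anchors
plus 3 × 7 = 21 intermediates: 24 scenarios.

Two construction modes are supported:

``override``
    Targeted-group shares (legumes and the three meats) are taken from an
    explicit per-scenario table.  This is the default: the published
    intermediate compositions follow an irregular hand-crafted ladder, so
    the authoritative values are data, not a formula.  A complete override
    schedule can be derived from a partial one with
    :func:`complete_overrides`, which fills unprinted scenarios by
    piecewise-linear interpolation between the known ones (filled rows are
    flagged as interpolated).

``linear``
    A documented convenience approximation: targeted meats move linearly
    from the segment's start anchor to its end anchor and the removed meat
    mass is credited 1:1 to legumes.

In both modes the groups not specified for a scenario are pinned to the
feasible anchor's values (the design raises fruits, vegetables, whole
grains and fish to feasible levels from S2 onward), and any residual mass
imbalance is absorbed by refined grains so that every scenario conserves
the 1800 g total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model import (
    ALL_MODELS,
    ConsumptionModel,
    DietComposition,
    DietScenario,
    canonical_group,
    validate_composition,
)
from .errors import (
    MassImbalanceError,
    ScheduleIncompleteError,
    SumNotOneError,
)

#: Groups an override row may pin (the substitution-active groups).
OVERRIDE_GROUPS: tuple[str, ...] = (
    "legumes",
    "processed meat",
    "red meat",
    "white meat",
)

#: Group that absorbs residual mass so each scenario sums to the diet total.
RESIDUAL_GROUP = "refined grains"

ANCHOR_IDS = ("S1", "S5", "S10")
ANCHOR_FLAGS = {"S1": "current", "S5": "feasible", "S10": "optimal"}


@dataclass(frozen=True)
class AnchorSet:
    """The current / feasible / optimal anchor compositions."""

    current: DietComposition
    feasible: DietComposition
    optimal: DietComposition

    def __post_init__(self) -> None:
        for c in (self.current, self.feasible, self.optimal):
            validate_composition(c)
        if not (
            self.current.total_mass_g
            == self.feasible.total_mass_g
            == self.optimal.total_mass_g
        ):
            raise SumNotOneError(
                "anchor diets must share one total mass", code="MASS_IMBALANCE"
            )


@dataclass(frozen=True)
class StepSchedule:
    """How intermediate scenarios are placed between the anchors.

    ``overrides`` maps scenario ids (e.g. ``"S2M1"``) to fractional shares
    of the substitution-active groups.  ``n_intermediate_low`` intermediates
    sit between current and feasible (S2–S4 by default),
    ``n_intermediate_high`` between feasible and optimal (S6–S9).
    """

    mode: str = "override"  # override | linear
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_intermediate_low: int = 3
    n_intermediate_high: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("override", "linear"):
            raise ScheduleIncompleteError(
                f"unknown schedule mode {self.mode!r}", code="BAD_CONFIG"
            )
        canon: dict[str, dict[str, float]] = {}
        for sid, shares in self.overrides.items():
            row = {canonical_group(g): float(v) for g, v in shares.items()}
            for g, v in row.items():
                if not (0.0 <= v <= 1.0):
                    raise ScheduleIncompleteError(
                        f"override {sid}/{g}: share {v} outside [0, 1]",
                        code="BAD_CONFIG",
                    )
            canon[sid] = row
        object.__setattr__(self, "overrides", canon)


def scenario_ids(
    models: Sequence[ConsumptionModel] = ALL_MODELS,
    n_intermediate_low: int = 3,
    n_intermediate_high: int = 4,
) -> list[str]:
    """Scenario ids in ladder order (anchors shared across models)."""
    low = range(2, 2 + n_intermediate_low)
    high = range(6, 6 + n_intermediate_high)
    ids = ["S1"]
    ids += [f"S{k}{m.model_id}" for k in low for m in models]
    ids += ["S5"]
    ids += [f"S{k}{m.model_id}" for k in high for m in models]
    ids += ["S10"]
    return ids


def _scenario_number(sid: str) -> int:
    body = sid[1:].split("M")[0]
    return int(body)


def _linear_targets(
    anchors: AnchorSet,
    model: ConsumptionModel,
    number: int,
    n_low: int,
    n_high: int,
) -> dict[str, float]:
    """Targeted-group shares for one linear-mode intermediate scenario."""
    cur, feas, opt = anchors.current, anchors.feasible, anchors.optimal
    if 2 <= number <= 1 + n_low:
        start, end = cur, feas
        frac = (number - 1) / (n_low + 1)
    else:
        start, end = feas, opt
        frac = (number - 5) / (n_high + 1)
    shares: dict[str, float] = {}
    removed = 0.0
    for g in model.targeted_groups:
        s = start.share(g) + frac * (end.share(g) - start.share(g))
        removed += start.share(g) - s
        shares[g] = s
    # 1:1 mass credit of removed meat to legumes
    shares["legumes"] = start.share("legumes") + removed
    return shares


def _compose(
    anchors: AnchorSet, pinned: Mapping[str, float]
) -> DietComposition:
    """Build a full composition: feasible base + pinned groups + residual."""
    shares = dict(anchors.feasible.shares)
    for g in anchors.current.shares:
        shares.setdefault(g, 0.0)
    shares.update({canonical_group(g): v for g, v in pinned.items()})
    residual = 1.0 - sum(v for g, v in shares.items() if g != RESIDUAL_GROUP)
    if residual < -1e-9:
        raise MassImbalanceError(
            f"pinned shares exceed total mass by {-residual:.4%}"
        )
    shares[RESIDUAL_GROUP] = max(residual, 0.0)
    return validate_composition(
        DietComposition(shares, total_mass_g=anchors.feasible.total_mass_g)
    )


def build_scenarios(
    anchors: AnchorSet,
    models: Sequence[ConsumptionModel] = ALL_MODELS,
    schedule: StepSchedule | None = None,
) -> list[DietScenario]:
    """Construct the scenario ladder between the anchors.

    Returns the three shared anchors plus, for each model, the scheduled
    intermediates — 24 scenarios under the default design.  Every scenario
    conserves the anchors' total daily mass.
    """
    schedule = schedule or StepSchedule(mode="linear")
    n_low, n_high = schedule.n_intermediate_low, schedule.n_intermediate_high

    out = [
        DietScenario("S1", anchors.current, "current"),
    ]
    for sid in scenario_ids(models, n_low, n_high):
        if sid in ANCHOR_IDS:
            continue
        number = _scenario_number(sid)
        model = next(m for m in models if sid.endswith(m.model_id))
        if schedule.mode == "override":
            if sid not in schedule.overrides:
                raise ScheduleIncompleteError(
                    f"override schedule is missing scenario {sid}"
                )
            pinned = schedule.overrides[sid]
        else:
            pinned = _linear_targets(anchors, model, number, n_low, n_high)
        out.append(DietScenario(sid, _compose(anchors, pinned), "intermediate"))

    out.append(DietScenario("S5", anchors.feasible, "feasible"))
    out.append(DietScenario("S10", anchors.optimal, "optimal"))
    order = {sid: i for i, sid in enumerate(scenario_ids(models, n_low, n_high))}
    out.sort(key=lambda s: order[s.scenario_id])
    return out


def check_anchor_midpoint(anchors: AnchorSet) -> dict[str, float]:
    """Per-group |feasible − (current + optimal)/2| in percent-of-mass units."""
    groups = (
        set(anchors.current.shares)
        | set(anchors.feasible.shares)
        | set(anchors.optimal.shares)
    )
    return {
        g: abs(
            anchors.feasible.share(g)
            - (anchors.current.share(g) + anchors.optimal.share(g)) / 2.0
        )
        * 100.0
        for g in sorted(groups)
    }


def complete_overrides(
    printed: Mapping[str, Mapping[str, float]],
    models: Sequence[ConsumptionModel] = ALL_MODELS,
    n_intermediate_low: int = 3,
    n_intermediate_high: int = 4,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Fill a partial override table to cover every intermediate scenario.

    ``printed`` maps scenario ids (anchor ids apply to all models) to
    fractional shares of the substitution-active groups.  Missing scenarios
    are filled per model and group by piecewise-linear interpolation over
    the scenario number between the nearest known scenarios; the anchors
    (S1 and S10, plus S5 when present) always serve as end knots.

    Returns the completed override map and a provenance map
    (scenario id → ``"printed"`` or ``"interpolated"``).
    """
    canon_printed = {
        sid: {canonical_group(g): float(v) for g, v in shares.items()}
        for sid, shares in printed.items()
    }
    completed: dict[str, dict[str, float]] = {}
    provenance: dict[str, str] = {}
    for model in models:
        # knots indexed by scenario number, for this model
        knots: dict[int, Mapping[str, float]] = {}
        for sid, shares in canon_printed.items():
            if sid in ANCHOR_IDS:
                knots[_scenario_number(sid)] = shares
            elif sid.endswith(model.model_id):
                knots[_scenario_number(sid)] = shares
        if 1 not in knots or 10 not in knots:
            raise ScheduleIncompleteError(
                "interpolation needs at least the S1 and S10 anchors"
            )
        xs = sorted(knots)
        numbers = list(range(2, 2 + n_intermediate_low)) + list(
            range(6, 6 + n_intermediate_high)
        )
        for number in numbers:
            sid = f"S{number}{model.model_id}"
            if number in knots:
                completed[sid] = dict(knots[number])
                provenance[sid] = "printed"
                continue
            row: dict[str, float] = {}
            for g in OVERRIDE_GROUPS:
                ys = [float(knots[x].get(g, 0.0)) for x in xs]
                row[g] = float(np.interp(number, xs, ys))
            completed[sid] = row
            provenance[sid] = "interpolated"
    return completed, provenance
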