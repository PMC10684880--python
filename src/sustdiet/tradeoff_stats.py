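"""Statistics over scenario score tables: correlations, subgroup summaries,
rankings and nutrition-environment trade-offs.

The scenario score table is a pandas DataFrame with one row per scenario,
a ``scenario_id`` column, nutrition score columns (``scaled_fcs``,
``heni_minutes``) and optionally one column per environmental indicator.
Subset statistics use the sample (n-1) standard deviation; scenario
rankings use average ranks for ties and the Kruskal-Wallis H statistic
with tie correction for grouped comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    EmptySubsetError,
    EmptyTableError,
    LengthMismatchError,
    MissingImpactsError,
    ZeroVarianceError,
)


@dataclass(frozen=True)
class SubsetSpec:
    """An explicit, named list of scenario ids."""

    label: str
    scenario_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_ids", tuple(self.scenario_ids))


def _indexed(t: pd.DataFrame) -> pd.DataFrame:
    if "scenario_id" in t.columns:
        return t.set_index("scenario_id")
    return t


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise LengthMismatchError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise LengthMismatchError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("both series need nonzero variance")
    return float(sps.pearsonr(x, y).statistic)


def subset_stats(
    t: pd.DataFrame, s: SubsetSpec, column: str
) -> tuple[float, float]:
    """Mean and sample (n-1) SD of ``column`` over an explicit subset.

    A singleton subset returns ``(value, nan)`` with a warning: its sample
    SD is undefined.
    """
    df = _indexed(t)
    missing = [sid for sid in s.scenario_ids if sid not in df.index]
    if missing:
        raise EmptySubsetError(
            f"subset {s.label!r} references unknown scenarios {missing}"
        )
    if not s.scenario_ids:
        raise EmptySubsetError(f"subset {s.label!r} is empty")
    values = df.loc[list(s.scenario_ids), column].astype(float)
    if len(values) == 1:
        warnings.warn(
            f"subset {s.label!r} is a singleton; sample SD undefined",
            stacklevel=2,
        )
        return float(values.iloc[0]), float("nan")
    return float(values.mean()), float(values.std(ddof=1))


def count_above(t: pd.DataFrame, column: str, threshold: float) -> int:
    """Number of scenarios with ``column`` strictly above ``threshold``."""
    return int((_indexed(t)[column].astype(float) > threshold).sum())


def rank_scenarios(
    t: pd.DataFrame,
    column: str,
    direction: str = "desc",
    groups: pd.Series | dict | None = None,
) -> tuple[pd.Series, float | None]:
    """Rank scenarios on one column (1 = best; ties share average ranks).

    ``direction="desc"`` ranks the largest value best (scores);
    ``"asc"`` ranks the smallest best (impacts).  When ``groups`` labels
    the scenarios, the tie-corrected Kruskal-Wallis H statistic over those
    groups is returned as well.
    """
    df = _indexed(t)
    if df.empty:
        raise EmptyTableError("cannot rank an empty table")
    values = df[column].astype(float)
    ascending = direction == "asc"
    # rank 1 = best under the requested direction
    ranked = values.rank(ascending=ascending, method="average")
    h = None
    if groups is not None:
        labels = pd.Series(groups)
        labels = labels.reindex(values.index)
        n = len(values)
        # ranks ascending by value, as in the classical H formula
        r = values.rank(method="average")
        h = 0.0
        for _, idx in r.groupby(labels).groups.items():
            rj = r.loc[idx]
            h += len(rj) * (rj.mean() - (n + 1) / 2.0) ** 2
        h *= 12.0 / (n * (n + 1))
        # tie correction
        _, counts = np.unique(values.to_numpy(), return_counts=True)
        correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        if correction > 0:
            h /= correction
        else:
            h = 0.0  # all values identical
    return ranked, h


def tradeoff_table(
    t: pd.DataFrame, nutrition_column: str, indicator: str
) -> pd.DataFrame:
    """Dual-scale nutrition-vs-impact series with Pareto flags.

    A scenario is flagged ``pareto=True`` when no other scenario has both a
    strictly-or-equal better nutrition score and impact, with at least one
    strict improvement (i.e. it is not dominated).
    """
    df = _indexed(t)
    if indicator not in df.columns:
        raise MissingImpactsError(
            f"indicator column {indicator!r} missing from score table"
        )
    nut = df[nutrition_column].astype(float).to_numpy()
    imp = df[indicator].astype(float).to_numpy()
    n = len(df)
    flags = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (
            (nut >= nut[i]) & (imp <= imp[i]) & ((nut > nut[i]) | (imp < imp[i]))
        )
        if dominated.any():
            flags[i] = False
    out = pd.DataFrame(
        {
            "scenario_id": df.index,
            nutrition_column: nut,
            indicator: imp,
            "pareto": flags,
        }
    ).reset_index(drop=True)
    return out


def correlation_matrix(
    impacts: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r across indicator columns, with significance flags.

    Returns ``(r, significant)`` where ``significant`` holds two-sided
    p < alpha flags from the t transform of r.  Zero-variance columns yield
    NaN rows/columns and a warning rather than an error.
    """
    cols = list(impacts.columns)
    n = len(impacts)
    if n < 3:
        raise LengthMismatchError("need at least 3 scenarios")
    degenerate = [c for c in cols if np.ptp(impacts[c].astype(float)) == 0]
    if degenerate:
        warnings.warn(
            f"zero-variance columns {degenerate}: correlations set to NaN",
            stacklevel=2,
        )
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in degenerate or b in degenerate:
                r.loc[a, b] = r.loc[b, a] = math.nan
                continue
            res = sps.pearsonr(
                impacts[a].astype(float), impacts[b].astype(float)
            )
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            sig.loc[a, b] = sig.loc[b, a] = bool(res.pvalue < alpha)
    return r, sig


# ---------------------------------------------------------------------------
# Published-table statistics
# ---------------------------------------------------------------------------

#: Explicit subsets used in the headline statistics (prose set definitions
#: are inconsistent, so each statistic pins its own id list).
FCS_CURRENT_TO_FEASIBLE = SubsetSpec(
    "FCS: current diet through the last pre-feasible step",
    (
        "S1",
        "S2M1", "S2M2", "S2M3",
        "S3M1", "S3M2", "S3M3",
        "S4M1", "S4M2", "S4M3",
    ),
)
FEASIBLE_TO_OPTIMAL = SubsetSpec(
    "intermediates between feasible and optimal",
    (
        "S6M1", "S6M2", "S6M3",
        "S7M1", "S7M2", "S7M3",
        "S8M1", "S8M2", "S8M3",
        "S9M1", "S9M2", "S9M3",
    ),
)
HENI_CURRENT_TO_FEASIBLE_MEAN = SubsetSpec(
    "HENI mean: intermediates between current and feasible",
    (
        "S2M1", "S2M2", "S2M3",
        "S3M1", "S3M2", "S3M3",
        "S4M1", "S4M2", "S4M3",
    ),
)


def table1_statistics(t: pd.DataFrame) -> dict[str, float]:
    """Recompute the headline score-table statistics from a 24-row table.

    Expects columns ``scenario_id``, ``scaled_fcs`` and ``heni_minutes``.
    """
    fcs_low = subset_stats(t, FCS_CURRENT_TO_FEASIBLE, "scaled_fcs")
    fcs_high = subset_stats(t, FEASIBLE_TO_OPTIMAL, "scaled_fcs")
    heni_low_mean, _ = subset_stats(
        t, HENI_CURRENT_TO_FEASIBLE_MEAN, "heni_minutes"
    )
    _, heni_low_sd = subset_stats(t, FCS_CURRENT_TO_FEASIBLE, "heni_minutes")
    heni_high = subset_stats(t, FEASIBLE_TO_OPTIMAL, "heni_minutes")
    df = _indexed(t)
    r = pearson(df["scaled_fcs"], df["heni_minutes"])
    fcs_ranks, _ = rank_scenarios(t, "scaled_fcs", "desc")
    heni_ranks, _ = rank_scenarios(t, "heni_minutes", "desc")
    return {
        "fcs_mean_current_to_feasible": fcs_low[0],
        "fcs_sd_current_to_feasible": fcs_low[1],
        "fcs_mean_feasible_to_optimal": fcs_high[0],
        "fcs_sd_feasible_to_optimal": fcs_high[1],
        "heni_mean_current_to_feasible": heni_low_mean,
        "heni_sd_current_to_feasible": heni_low_sd,
        "heni_mean_feasible_to_optimal": heni_high[0],
        "heni_sd_feasible_to_optimal": heni_high[1],
        "pearson_fcs_heni": r,
        "count_fcs_above_71": float(count_above(t, "scaled_fcs", 71.0)),
        "rank_S1_fcs": float(fcs_ranks.loc["S1"]),
        "rank_S10_fcs": float(fcs_ranks.loc["S10"]),
        "rank_S1_heni": float(heni_ranks.loc["S1"]),
        "rank_S10_heni": float(heni_ranks.loc["S10"]),
    }
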