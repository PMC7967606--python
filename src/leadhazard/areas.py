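"""Aggregation of parcel scores to census geographies.

The area lead-risk score of a block, block group, or tract is the sum of
final parcel scores divided by the count of *all* residential parcels in
the unit -- post-1978 parcels count in the denominator with score 0, so a
neighborhood of new construction correctly reads as very low risk.
Units that house children but contain no classified residential parcels
(large apartment complexes, dormitories) are reported as No Data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "RISK_LEVELS",
    "LEVELS",
    "classify",
    "classify_series",
    "aggregate",
    "category_counts",
]

#: Risk categories from safest to most hazardous, plus the No Data flag.
RISK_LEVELS: tuple[str, ...] = ("Very Low", "Low", "Moderate", "High", "Very High")
CATEGORIES: tuple[str, ...] = RISK_LEVELS + ("No Data",)
LEVELS: tuple[str, ...] = ("block", "block_group", "tract")

# Score partition: {0} -> Very Low, (0,1) -> Low, [1,2) -> Moderate,
# [2,3) -> High, [3,inf) -> Very High.


def classify(mean_score: float) -> str:
    """Map an area mean score to its risk category."""
    s = float(mean_score)
    if not np.isfinite(s) or s < 0:
        raise ValueError(f"mean score must be finite and non-negative, got {s}")
    if s == 0:
        return "Very Low"
    if s < 1:
        return "Low"
    if s < 2:
        return "Moderate"
    if s < 3:
        return "High"
    return "Very High"


def classify_series(mean_scores: pd.Series) -> pd.Series:
    """Vectorised :func:`classify`; NaN maps to No Data."""
    s = mean_scores.to_numpy(dtype=float)
    neg = np.isfinite(s) & (s < 0)
    if neg.any():
        raise ValueError("mean scores must be non-negative")
    out = np.select(
        [np.isnan(s), s == 0, s < 1, s < 2, s < 3],
        ["No Data", "Very Low", "Low", "Moderate", "High"],
        default="Very High",
    )
    return pd.Series(out, index=mean_scores.index, name="category")


def aggregate(
    scores: pd.DataFrame,
    level: str,
    known_geo_ids: pd.Series | list[str] | None = None,
    child_geo_ids: pd.Series | list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate parcel final scores to one geography level.

    Parameters
    ----------
    scores
        Parcel score table with a ``final_score`` column and a
        ``{level}_id`` geography column (e.g. ``tract_id``).
    level
        One of ``block``, ``block_group``, ``tract``.
    known_geo_ids
        The full id universe for this level. Parcels referencing an id
        outside it raise a validation error listing the offenders.
    child_geo_ids
        Ids of units with resident children. Units with children but no
        parcels are emitted with ``No Data``; child-less parcel-less
        units are dropped.

    Returns
    -------
    DataFrame with columns ``geo_id, level, parcel_count, score_sum,
    mean_score, category``, sorted by ``geo_id``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    col = f"{level}_id"
    if col not in scores.columns:
        raise ValueError(f"score table has no {col!r} column")

    if known_geo_ids is not None:
        known = pd.Index(known_geo_ids)
        offenders = sorted(set(scores[col]) - set(known))
        if offenders:
            raise ValueError(
                f"parcels reference unknown {level} ids: {offenders[:10]}"
                + (" ..." if len(offenders) > 10 else "")
            )

    grouped = scores.groupby(col)["final_score"].agg(
        parcel_count="size", score_sum="sum"
    )
    grouped["mean_score"] = grouped["score_sum"] / grouped["parcel_count"]

    if child_geo_ids is not None:
        empty = pd.Index(child_geo_ids).unique().difference(grouped.index)
        if len(empty):
            filler = pd.DataFrame(
                {"parcel_count": 0, "score_sum": 0.0, "mean_score": np.nan},
                index=empty,
            )
            grouped = pd.concat([grouped, filler])

    grouped = grouped.sort_index()
    out = grouped.reset_index(names="geo_id")
    out.insert(1, "level", level)
    out["category"] = classify_series(out["mean_score"])
    return out


def category_counts(areas: pd.DataFrame) -> pd.DataFrame:
    """Count units per (level, category); rows for all categories, zero-filled."""
    if areas.empty:
        return pd.DataFrame(
            0, index=pd.Index(CATEGORIES, name="category"), columns=list(LEVELS)
        )
    tab = (
        areas.groupby(["category", "level"], observed=True)
        .size()
        .unstack("level", fill_value=0)
        .reindex(CATEGORIES, fill_value=0)
        .reindex(columns=[l for l in LEVELS if l in areas["level"].unique()], fill_value=0)
    )
    tab.index.name = "category"
    return tab
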