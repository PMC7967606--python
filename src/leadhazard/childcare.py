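"""Community lead-risk scoring for childcare centers.

Each center is scored by the residential parcels within a half-mile
buffer (planar Euclidean distance, closed disc): the sum of parcel final
scores divided by the count of all residential parcels in the buffer,
post-1978 parcels included as zeros. The score partition matches the
area classification, but the top category is labelled "Highest" in
childcare outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .areas import classify_series

__all__ = [
    "PRIORITY_LEVELS",
    "DEFAULT_RADIUS_MILES",
    "PROGRAM_TYPES",
    "score_centers",
    "tabulate_by_type",
]

DEFAULT_RADIUS_MILES = 0.5

#: Priority labels, most urgent first.
PRIORITY_LEVELS: tuple[str, ...] = (
    "Highest", "High", "Moderate", "Low", "Very Low", "No Data"
)

_AREA_TO_PRIORITY = {"Very High": "Highest"}

#: The seven certified childcare program types.
PROGRAM_TYPES: tuple[str, ...] = (
    "In Home Aide",
    "Licensed Childcare Center",
    "Licensed Type A Family Childcare Home",
    "Licensed Type B Family Childcare Home",
    "ODE Licensed Preschool",
    "ODE Licensed School Age Childcare",
    "Registered Day Camp",
)


def score_centers(
    centers: pd.DataFrame,
    scores: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_MILES,
) -> pd.DataFrame:
    """Score every childcare center by its buffered community risk.

    Parameters
    ----------
    centers
        Table with ``center_id, program_type, x, y`` (planar miles).
    scores
        Parcel score table with ``x, y, final_score``; coordinates must
        share the centers' planar mile frame.
    radius
        Buffer radius in miles; parcels at exactly ``radius`` are included.

    Returns
    -------
    DataFrame with ``center_id, program_type, n_parcels_in_buffer,
    score_sum, score, priority``; empty buffers get priority ``No Data``.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    out = centers[["center_id", "program_type"]].copy().reset_index(drop=True)
    n_centers = len(out)
    counts = np.zeros(n_centers, dtype=int)
    sums = np.zeros(n_centers, dtype=float)
    if n_centers and len(scores):
        tree = cKDTree(scores[["x", "y"]].to_numpy(dtype=float))
        final = scores["final_score"].to_numpy(dtype=float)
        hits = tree.query_ball_point(
            centers[["x", "y"]].to_numpy(dtype=float), r=radius
        )
        for i, idx in enumerate(hits):
            counts[i] = len(idx)
            sums[i] = final[idx].sum()
    out["n_parcels_in_buffer"] = counts
    out["score_sum"] = sums
    with np.errstate(invalid="ignore"):
        out["score"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    cat = classify_series(out["score"])
    out["priority"] = cat.map(lambda c: _AREA_TO_PRIORITY.get(c, c))
    return out


def tabulate_by_type(center_risks: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate program type against priority, with grand totals.

    Rows are the seven program types plus ``Total``; columns are the
    priority levels (only those observed, in urgency order) plus
    ``Grand Total``. Margins sum to the number of centers.
    """
    if center_risks.empty:
        tab = pd.DataFrame(0, index=list(PROGRAM_TYPES), columns=list(PRIORITY_LEVELS))
    else:
        tab = (
            center_risks.groupby(["program_type", "priority"], observed=True)
            .size()
            .unstack("priority", fill_value=0)
        )
        types = [t for t in PROGRAM_TYPES] + sorted(
            set(tab.index) - set(PROGRAM_TYPES)
        )
        tab = tab.reindex(types, fill_value=0)
        cols = [p for p in PRIORITY_LEVELS if p in tab.columns]
        tab = tab[cols]
    tab["Grand Total"] = tab.sum(axis=1)
    tab.loc["Total"] = tab.sum(axis=0)
    tab.index.name = "program_type"
    return tab
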