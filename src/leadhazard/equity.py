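"""Child exposure and racial-disparity analysis over area risk categories.

Cross-tabulates child population against neighborhood risk tiers,
decomposes the under-5 population by race across tiers, bands tracts by
non-white child share within risk strata, and fits the linear association
between tract risk and published opportunity indices (COI/HOI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .areas import RISK_LEVELS

__all__ = [
    "RACES",
    "HIGH_RISK",
    "OpportunityAssociation",
    "exposure_table",
    "race_risk_distribution",
    "nonwhite_share",
    "nonwhite_crosstab",
    "opportunity_association",
    "risk_race_association",
    "permutation_null",
    "priority_areas",
]

RACES: tuple[str, ...] = ("White", "Black", "Asian", "Hispanic", "Other")

#: The combined stratum of most concern: High plus Very High.
HIGH_RISK: tuple[str, str] = ("High", "Very High")

_RACE_COLS = {r: f"under5_{r.lower()}" for r in RACES}


def _category_map(areas: pd.DataFrame) -> pd.Series:
    return areas.set_index("geo_id")["category"]


def exposure_table(
    areas: pd.DataFrame, children: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Tabulate child counts and shares per risk category.

    Parameters
    ----------
    areas
        Area risk table (``geo_id, category``) at one geography level.
    children
        Child-population rows at the same level, with ``geo_id,
        under5_total`` and optionally ``under18_total``.

    Returns
    -------
    (table, meta)
        ``table`` has one row per risk category plus ``Total``, with
        count and share (percent) columns; shares are exact ratios of
        the counts. ``meta`` reports the combined High + Very High
        shares, the geography level, and any No Data children counted
        separately from the shares.
    """
    cat = _category_map(areas)
    unknown = sorted(set(children["geo_id"]) - set(cat.index))
    if unknown:
        raise ValueError(f"child records reference unknown geo ids: {unknown[:10]}")

    df = children.copy()
    df["category"] = df["geo_id"].map(cat).to_numpy()
    has_u18 = "under18_total" in df.columns and df["under18_total"].notna().all()

    agg_cols = {"under5_total": "sum"}
    if has_u18:
        agg_cols["under18_total"] = "sum"
    by_cat = df.groupby("category", observed=True).agg(agg_cols)

    nodata = by_cat.loc["No Data"] if "No Data" in by_cat.index else None
    body = by_cat.reindex(RISK_LEVELS, fill_value=0)

    table = pd.DataFrame(index=pd.Index(list(RISK_LEVELS) + ["Total"], name="category"))
    total5 = body["under5_total"].sum()
    table["under5_count"] = list(body["under5_total"]) + [total5]
    table["under5_share"] = 100.0 * table["under5_count"] / total5 if total5 else 0.0
    meta = {
        "level": str(children["level"].iloc[0]) if "level" in children.columns else None,
        "high_very_high_under5_share": float(
            100.0 * body.loc[list(HIGH_RISK), "under5_total"].sum() / total5
        )
        if total5
        else np.nan,
        "no_data_under5": int(nodata["under5_total"]) if nodata is not None else 0,
    }
    if has_u18:
        total18 = body["under18_total"].sum()
        table["under18_count"] = list(body["under18_total"]) + [total18]
        table["under18_share"] = (
            100.0 * table["under18_count"] / total18 if total18 else 0.0
        )
        meta["high_very_high_under18_share"] = (
            float(100.0 * body.loc[list(HIGH_RISK), "under18_total"].sum() / total18)
            if total18
            else np.nan
        )
    return table, meta


def race_risk_distribution(
    tract_areas: pd.DataFrame, children_tracts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of under-5 children of each race across risk tiers.

    Returns
    -------
    (counts, summary)
        ``counts``: race x category count table (columns the five risk
        tiers). ``summary`` per race: total under-5, percent living in
        High + Very High tracts, and the race's share of all high-risk
        children (Black high-risk count / all high-risk count etc.).
    """
    cat = _category_map(tract_areas)
    df = children_tracts.copy()
    race_cols = [c for c in _RACE_COLS.values() if c in df.columns]
    if not race_cols:
        raise ValueError("tract child table carries no under5_<race> columns")
    by_race = df[race_cols].sum(axis=1)
    bad = df.loc[by_race.round(6) > df["under5_total"] + 1e-9, "geo_id"]
    if len(bad):
        raise ValueError(
            f"race counts exceed under5_total in tracts: {sorted(bad)[:10]}"
        )
    df["category"] = df["geo_id"].map(cat).to_numpy()
    counts = (
        df.groupby("category", observed=True)[race_cols]
        .sum()
        .reindex(RISK_LEVELS, fill_value=0)
        .T
    )
    counts.index = [r for r in RACES if _RACE_COLS[r] in race_cols]
    counts.index.name = "race"

    high = counts[list(HIGH_RISK)].sum(axis=1)
    total_high = high.sum()
    summary = pd.DataFrame(
        {
            "under5_total": counts.sum(axis=1),
            "high_risk_count": high,
            "high_risk_share_pct": 100.0 * high / counts.sum(axis=1).replace(0, np.nan),
            "share_of_high_risk_children_pct": 100.0 * high / total_high
            if total_high
            else np.nan,
        }
    )
    return counts, summary


def nonwhite_share(children_tracts: pd.DataFrame) -> pd.Series:
    """Non-white share of under-5 children per tract: 1 - White/total."""
    w = children_tracts[_RACE_COLS["White"]].to_numpy(dtype=float)
    t = children_tracts["under5_total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(t > 0, 1.0 - w / t, np.nan)
    return pd.Series(share, index=children_tracts["geo_id"].to_numpy(), name="nonwhite_share")

#: Default non-white-share bands; >75% nests inside >50%.
DEFAULT_BANDS: dict[str, tuple[float, float, bool]] = {
    "<=10%": (0.0, 0.10, True),     # (lo, hi, hi_inclusive); lo exclusive except 0
    "10-50%": (0.10, 0.50, True),
    ">50%": (0.50, np.inf, False),
    ">75%": (0.75, np.inf, False),
}

DEFAULT_STRATA: dict[str, tuple[str, ...]] = {
    "High + Very High": HIGH_RISK,
    "Low": ("Low",),
}


def nonwhite_crosstab(
    tract_areas: pd.DataFrame,
    children_tracts: pd.DataFrame,
    bands: dict[str, tuple[float, float, bool]] = DEFAULT_BANDS,
    strata: dict[str, tuple[str, ...]] = DEFAULT_STRATA,
) -> tuple[pd.DataFrame, dict]:
    """Fraction of tracts per risk stratum falling in non-white-share bands.

    Bands may nest (the default ``>75%`` is a subset of ``>50%``), so row
    fractions need not sum to 100; the metadata declares the band
    definitions explicitly.
    """
    cat = _category_map(tract_areas)
    share = nonwhite_share(children_tracts)
    tract_cat = children_tracts["geo_id"].map(cat)

    rows = {}
    empty = []
    for name, cats in strata.items():
        in_stratum = tract_cat.isin(cats).to_numpy() & share.notna().to_numpy()
        n = int(in_stratum.sum())
        if n == 0:
            empty.append(name)
            continue
        s = share.to_numpy()[in_stratum]
        row = {"n_tracts": n}
        for bname, (lo, hi, hi_incl) in bands.items():
            inside = (s > lo) | ((lo == 0.0) & (s == 0.0))
            inside &= (s <= hi) if hi_incl else np.ones_like(inside)
            if np.isfinite(hi) and not hi_incl:
                inside &= s < hi
            row[f"pct {bname}"] = 100.0 * inside.sum() / n
        rows[name] = row
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab.index.name = "stratum"
    meta = {
        "bands": {k: {"lo": v[0], "hi": v[1], "hi_inclusive": v[2]} for k, v in bands.items()},
        "nesting_note": "bands may overlap; fractions within a stratum need not sum to 100",
        "empty_strata": empty,
    }
    return tab, meta


@dataclass(frozen=True)
class OpportunityAssociation:
    """OLS fit of an opportunity index on tract mean lead-risk score."""

    index_name: str
    slope: float
    intercept: float
    r_squared: float
    n_tracts: int


def opportunity_association(
    tract_scores: pd.DataFrame, opportunity: pd.DataFrame
) -> list[OpportunityAssociation]:
    """Regress each opportunity index (coi, hoi) on tract mean risk score.

    Tracts are paired by id; tracts missing from either table are
    dropped. Requires at least 3 paired tracts and non-degenerate score
    variance.
    """
    merged = tract_scores[["geo_id", "mean_score"]].merge(
        opportunity, left_on="geo_id", right_on="tract_id", how="inner"
    )
    merged = merged.dropna(subset=["mean_score"])
    if len(merged) < 3:
        raise ValueError(
            f"need at least 3 tracts with both score and index, got {len(merged)}"
        )
    x = merged["mean_score"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("tract scores have zero variance; the fit is undefined")
    out = []
    for col in ("coi", "hoi"):
        if col not in merged.columns:
            continue
        y = merged[col].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        out.append(
            OpportunityAssociation(
                index_name=col.upper(),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue**2),
                n_tracts=len(merged),
            )
        )
    return out


def risk_race_association(
    tract_scores: pd.DataFrame, children_tracts: pd.DataFrame
) -> tuple[float, float]:
    """Spearman rank correlation between tract risk and non-white share.

    Returns (rho, p_value) over tracts present in both tables.
    """
    share = nonwhite_share(children_tracts)
    merged = tract_scores.set_index("geo_id")["mean_score"].to_frame().join(
        share, how="inner"
    ).dropna()
    rho, p = stats.spearmanr(merged["mean_score"], merged["nonwhite_share"])
    return float(rho), float(p)


def permutation_null(
    tract_scores: pd.DataFrame,
    children_tracts: pd.DataFrame,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """P-values of the risk/non-white association under label shuffling.

    Randomly permuting which tract gets which racial composition breaks
    the spatial coupling, so the returned p-values should look uniform.
    """
    if rng is None:
        rng = np.random.default_rng()
    share = nonwhite_share(children_tracts)
    merged = tract_scores.set_index("geo_id")["mean_score"].to_frame().join(
        share, how="inner"
    ).dropna()
    x = merged["mean_score"].to_numpy()
    y = merged["nonwhite_share"].to_numpy()
    pvals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        _, pvals[i] = stats.spearmanr(x, rng.permutation(y))
    return pvals


def priority_areas(
    bg_areas: pd.DataFrame,
    children_bg: pd.DataFrame,
    child_tiers: tuple[float, float] = (1 / 3, 2 / 3),
) -> pd.DataFrame:
    """High-risk units with relatively many young children.

    Block groups in High or Very High risk are intersected with
    child-concentration tiers: under-5 counts at or above the upper
    quantile (default top tertile) are "High consideration", between the
    two quantiles "Moderate consideration". Returns the flagged units
    with their risk category, child count, and consideration tier.
    """
    counts = children_bg.set_index("geo_id")["under5_total"]
    lo_q, hi_q = counts.quantile(list(child_tiers))
    merged = bg_areas.merge(
        counts.rename("under5_total"), left_on="geo_id", right_index=True, how="inner"
    )
    risky = merged[merged["category"].isin(HIGH_RISK)].copy()
    tier = np.select(
        [risky["under5_total"] >= hi_q, risky["under5_total"] >= lo_q],
        ["High consideration", "Moderate consideration"],
        default="",
    )
    risky["consideration"] = tier
    return risky[risky["consideration"] != ""].reset_index(drop=True)
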