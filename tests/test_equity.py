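"""Exposure tables, race-risk distributions, and opportunity-index fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leadhazard.equity import (
    exposure_table,
    nonwhite_crosstab,
    nonwhite_share,
    opportunity_association,
    permutation_null,
    priority_areas,
    race_risk_distribution,
    risk_race_association,
)

CATS = ["Very High", "High", "Moderate", "Low", "Very Low"]


def _areas(categories, prefix="T"):
    return pd.DataFrame(
        {
            "geo_id": [f"{prefix}{i}" for i in range(len(categories))],
            "level": "tract",
            "category": categories,
            "mean_score": [
                {"Very High": 3.5, "High": 2.5, "Moderate": 1.5,
                 "Low": 0.5, "Very Low": 0.0, "No Data": np.nan}[c]
                for c in categories
            ],
        }
    )


def test_exposure_table_published_county_counts():
    """Feeding the published per-category child counts through the table
    reproduces the combined high-risk shares of 27.5% (under 5) and
    27.1% (under 18)."""
    areas = _areas(CATS)
    children = pd.DataFrame(
        {
            "geo_id": [f"T{i}" for i in range(5)],
            "level": "tract",
            "under5_total": [9526, 15361, 17320, 45780, 2494],
            "under18_total": [30569, 50084, 52944, 157185, 6789],
        }
    )
    table, meta = exposure_table(areas, children)
    assert table.loc["Total", "under5_count"] == 90481
    assert table.loc["Total", "under18_count"] == 297571
    assert meta["high_very_high_under5_share"] == pytest.approx(27.5, abs=0.05)
    assert meta["high_very_high_under18_share"] == pytest.approx(27.1, abs=0.05)
    assert table["under5_share"].iloc[:5].sum() == pytest.approx(100.0)
    assert table.loc["Very High", "under5_share"] == pytest.approx(10.5, abs=0.05)


def test_exposure_table_single_category():
    areas = _areas(["High", "High"])
    children = pd.DataFrame(
        {"geo_id": ["T0", "T1"], "level": "tract", "under5_total": [10, 20]}
    )
    table, meta = exposure_table(areas, children)
    assert table.loc["High", "under5_share"] == pytest.approx(100.0)
    assert (table.loc[["Very High", "Moderate", "Low", "Very Low"], "under5_share"] == 0).all()


def test_exposure_table_unknown_geo_id():
    with pytest.raises(ValueError, match="ZZ"):
        exposure_table(
            _areas(["High"]),
            pd.DataFrame({"geo_id": ["ZZ"], "level": "tract", "under5_total": [1]}),
        )


def _race_children(rows):
    df = pd.DataFrame(rows)
    df["level"] = "tract"
    return df


def test_race_distribution_published_high_risk_counts():
    """The published pair (Black high-risk 11,484 of 24,486) yields a
    46.9% Black share of high-risk children."""
    areas = _areas(["High", "Low"])
    children = _race_children(
        [
            {"geo_id": "T0", "under5_total": 24486, "under5_white": 24486 - 11484 - 9002,
             "under5_black": 11484, "under5_asian": 4000, "under5_hispanic": 4002,
             "under5_other": 1000},
            {"geo_id": "T1", "under5_total": 100, "under5_white": 100, "under5_black": 0,
             "under5_asian": 0, "under5_hispanic": 0, "under5_other": 0},
        ]
    )
    _, summary = race_risk_distribution(areas, children)
    assert summary.loc["Black", "share_of_high_risk_children_pct"] == pytest.approx(
        100 * 11484 / 24486, abs=1e-9
    )
    assert summary.loc["Black", "share_of_high_risk_children_pct"] == pytest.approx(46.9, abs=0.05)


def test_race_distribution_validates_counts():
    areas = _areas(["High"])
    children = _race_children(
        [{"geo_id": "T0", "under5_total": 5, "under5_white": 4, "under5_black": 4,
          "under5_asian": 0, "under5_hispanic": 0, "under5_other": 0}]
    )
    with pytest.raises(ValueError, match="exceed"):
        race_risk_distribution(areas, children)


def test_race_distribution_single_race_equals_overall():
    areas = _areas(["High", "Low", "Moderate"])
    children = _race_children(
        [
            {"geo_id": "T0", "under5_total": 30, "under5_white": 30},
            {"geo_id": "T1", "under5_total": 50, "under5_white": 50},
            {"geo_id": "T2", "under5_total": 20, "under5_white": 20},
        ]
    )
    counts, _ = race_risk_distribution(areas, children)
    assert counts.loc["White"].sum() == 100
    assert counts.loc["White", "High"] == 30
    assert counts.loc["White", "Low"] == 50


def test_synthetic_county_minority_overexposure():
    """With the default positive race gradient, Black and Hispanic
    high-risk shares exceed White's across seeds."""
    from leadhazard.areas import aggregate
    from leadhazard.scoring import score_table
    from leadhazard.synthetic import SyntheticConfig, generate_county

    for seed in range(1, 11):
        c = generate_county(SyntheticConfig(seed=seed, n_parcels=5000))
        scores, _ = score_table(c["parcels"])
        ta = aggregate(scores, "tract")
        kids = c["children"]
        _, summary = race_risk_distribution(ta, kids[kids["level"] == "tract"])
        assert summary.loc["Black", "high_risk_share_pct"] > summary.loc["White", "high_risk_share_pct"]
        assert summary.loc["Hispanic", "high_risk_share_pct"] > summary.loc["White", "high_risk_share_pct"]


def test_nonwhite_crosstab_hand_count():
    areas = _areas(["High", "High", "High", "High"])
    children = _race_children(
        [
            {"geo_id": f"T{i}", "under5_total": 100, "under5_white": int(100 * (1 - s))}
            for i, s in enumerate([0.6, 0.7, 0.4, 0.9])
        ]
    )
    tab, meta = nonwhite_crosstab(areas, children)
    row = tab.loc["High + Very High"]
    assert row["n_tracts"] == 4
    assert row["pct >50%"] == pytest.approx(75.0)
    assert row["pct >75%"] == pytest.approx(25.0)
    assert meta["empty_strata"] == ["Low"]


def test_nonwhite_crosstab_all_nonwhite():
    areas = _areas(["High", "Low"])
    children = _race_children(
        [
            {"geo_id": "T0", "under5_total": 50, "under5_white": 0},
            {"geo_id": "T1", "under5_total": 50, "under5_white": 0},
        ]
    )
    tab, _ = nonwhite_crosstab(areas, children)
    assert (tab["pct >50%"] == 100.0).all()


def test_opportunity_fit_noiseless_line():
    scores = pd.DataFrame({"geo_id": [f"T{i}" for i in range(10)],
                           "mean_score": np.linspace(0, 4, 10)})
    opp = pd.DataFrame({"tract_id": scores["geo_id"],
                        "coi": 80 - 12 * scores["mean_score"],
                        "hoi": 75 - 9 * scores["mean_score"]})
    fits = {f.index_name: f for f in opportunity_association(scores, opp)}
    assert fits["COI"].r_squared == pytest.approx(1.0)
    assert fits["COI"].slope == pytest.approx(-12.0)
    assert fits["HOI"].slope == pytest.approx(-9.0)


def test_opportunity_fit_against_closed_form():
    """Five hand-picked points: R^2 equals the squared Pearson formula
    computed from raw sums."""
    x = np.array([0.2, 1.1, 1.9, 2.8, 3.5])
    y = np.array([70.0, 61.0, 55.5, 38.0, 30.0])
    n = len(x)
    sxy = n * (x * y).sum() - x.sum() * y.sum()
    sxx = n * (x * x).sum() - x.sum() ** 2
    syy = n * (y * y).sum() - y.sum() ** 2
    r2_expected = sxy**2 / (sxx * syy)
    slope_expected = sxy / sxx

    scores = pd.DataFrame({"geo_id": [f"T{i}" for i in range(n)], "mean_score": x})
    opp = pd.DataFrame({"tract_id": scores["geo_id"], "coi": y})
    (fit,) = opportunity_association(scores, opp)
    assert fit.r_squared == pytest.approx(r2_expected, abs=1e-9)
    assert fit.slope == pytest.approx(slope_expected, abs=1e-9)
    assert np.sign(fit.slope) == np.sign(sxy)


def test_opportunity_fit_affine_invariance():
    x = np.array([0.2, 1.1, 1.9, 2.8, 3.5, 0.9])
    y = np.array([70.0, 61.0, 55.5, 38.0, 30.0, 66.0])
    scores = pd.DataFrame({"geo_id": [f"T{i}" for i in range(6)], "mean_score": x})
    base = opportunity_association(
        scores, pd.DataFrame({"tract_id": scores["geo_id"], "coi": y})
    )[0]
    rescaled = opportunity_association(
        scores, pd.DataFrame({"tract_id": scores["geo_id"], "coi": 3.0 * y + 100.0})
    )[0]
    assert rescaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)


def test_opportunity_fit_refuses_degenerate_inputs():
    scores = pd.DataFrame({"geo_id": ["T0", "T1"], "mean_score": [1.0, 2.0]})
    opp = pd.DataFrame({"tract_id": ["T0", "T1"], "coi": [1.0, 2.0]})
    with pytest.raises(ValueError, match="3 tracts"):
        opportunity_association(scores, opp)
    scores3 = pd.DataFrame({"geo_id": list("abc"), "mean_score": [1.0, 1.0, 1.0]})
    opp3 = pd.DataFrame({"tract_id": list("abc"), "coi": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="variance"):
        opportunity_association(scores3, opp3)


def test_permutation_destroys_association(tract_areas, tract_children, rng):
    """The seeded county shows a strong positive risk/non-white-share
    association; shuffling tract race labels removes it."""
    rho, p = risk_race_association(tract_areas, tract_children)
    assert rho > 0
    assert p < 0.01
    pvals = permutation_null(tract_areas, tract_children, n_shuffles=100, rng=rng)
    assert (pvals > 0.05).mean() >= 0.90


def test_share_columns_are_exact_ratios(tract_areas, tract_children):
    table, _ = exposure_table(tract_areas, tract_children)
    total = table.loc["Total", "under5_count"]
    np.testing.assert_allclose(
        table["under5_share"], 100.0 * table["under5_count"] / total, rtol=1e-12
    )


def test_priority_areas_flags_high_risk_high_child_units():
    bg_areas = pd.DataFrame(
        {
            "geo_id": ["G0", "G1", "G2", "G3"],
            "level": "block_group",
            "mean_score": [2.5, 3.1, 0.5, 2.2],
            "category": ["High", "Very High", "Low", "High"],
        }
    )
    children = pd.DataFrame(
        {"geo_id": ["G0", "G1", "G2", "G3"], "level": "block_group",
         "under5_total": [90, 80, 70, 5]}
    )
    out = priority_areas(bg_areas, children)
    assert set(out["geo_id"]) == {"G0", "G1"}
    assert (out["consideration"] == "High consideration").all()
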