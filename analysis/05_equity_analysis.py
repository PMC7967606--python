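#!/usr/bin/env python
"""Child exposure, racial disparity, and opportunity-index association.

Tract-level analysis of the synthetic county: the exposure table (child
counts per risk tier), the race x risk distribution, the non-white-share
crosstab by risk stratum, the OLS fits of COI/HOI on tract risk, and a
permutation check that the risk/race coupling is real rather than an
artifact of the statistic. Also writes a lead-risk vs COI/HOI scatter to
results/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from leadhazard.equity import (
    exposure_table,
    nonwhite_crosstab,
    opportunity_association,
    permutation_null,
    race_risk_distribution,
    risk_race_association,
)
from leadhazard.io import read_children, read_opportunity

RESULTS = Path("results")


def main() -> None:
    tract_areas = pd.read_csv(RESULTS / "area_scores_tract.csv")
    children = read_children(RESULTS / "synthetic" / "children.csv")
    tract_children = children[children["level"] == "tract"]
    opportunity = read_opportunity(RESULTS / "synthetic" / "opportunity.csv")

    table, meta = exposure_table(tract_areas, tract_children)
    table.to_csv(RESULTS / "exposure_table.csv")
    print("children per risk tier (tract level):")
    print(table.round(1).to_string())
    print(f"-> {meta['high_very_high_under5_share']:.1f}% of under-5 children live "
          f"in High or Very High risk tracts")

    counts, summary = race_risk_distribution(tract_areas, tract_children)
    counts.to_csv(RESULTS / "race_risk.csv")
    summary.to_csv(RESULTS / "race_risk_summary.csv")
    print("\nper-race share living in High + Very High tracts (%):")
    print(summary["high_risk_share_pct"].round(1).to_string())

    crosstab, _ = nonwhite_crosstab(tract_areas, tract_children)
    crosstab.to_csv(RESULTS / "nonwhite_crosstab.csv")
    print("\ntracts by non-white under-5 share within risk strata (%):")
    print(crosstab.round(1).to_string())

    rho, p = risk_race_association(tract_areas, tract_children)
    pvals = permutation_null(tract_areas, tract_children, n_shuffles=100,
                             rng=np.random.default_rng(0))
    print(f"\nrisk vs non-white share: Spearman rho={rho:.2f} (p={p:.1e}); "
          f"after shuffling race labels, {100 * (pvals > 0.05).mean():.0f}% of 100 "
          f"permutations show no association (p>0.05)")

    fits = opportunity_association(tract_areas, opportunity)
    (RESULTS / "opportunity_fit.json").write_text(
        json.dumps([f.__dict__ for f in fits], indent=2)
    )
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    merged = tract_areas.merge(opportunity, left_on="geo_id", right_on="tract_id")
    for ax, fit, col in zip(axes, fits, ("coi", "hoi")):
        ax.scatter(merged["mean_score"], merged[col], s=12, alpha=0.7)
        xs = np.linspace(merged["mean_score"].min(), merged["mean_score"].max(), 20)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson")
        ax.set_xlabel("tract mean lead-risk score")
        ax.set_ylabel(fit.index_name)
        ax.set_title(f"{fit.index_name}: R$^2$={fit.r_squared:.2f}")
        print(f"{fit.index_name}: slope={fit.slope:.2f}, R^2={fit.r_squared:.2f} "
              f"(n={fit.n_tracts} tracts)")
    (RESULTS / "figures").mkdir(exist_ok=True, parents=True)
    fig.tight_layout()
    fig.savefig(RESULTS / "figures" / "opportunity_vs_risk.png", dpi=120)


if __name__ == "__main__":
    main()
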