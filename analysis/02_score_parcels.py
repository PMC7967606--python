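#!/usr/bin/env python
"""Score every residential parcel for lead-paint hazard.

Reads results/synthetic/parcels.csv, applies the age-tier + value-tier
cumulative score and the grade modifier, and writes
results/parcel_scores.csv (plus a rejects report). Prints the exclusion
accounting and the final-score distribution.
"""

from pathlib import Path

import pandas as pd

from leadhazard.io import read_parcels
from leadhazard.scoring import score_table

RESULTS = Path("results")


def main() -> None:
    parcels, read_rejects = read_parcels(RESULTS / "synthetic" / "parcels.csv")
    scores, rejects = score_table(parcels)
    rejects = pd.concat([read_rejects, rejects], ignore_index=True)

    scores.to_csv(RESULTS / "parcel_scores.csv", index=False)
    rejects.to_csv(RESULTS / "rejects.csv", index=False)

    n = len(scores)
    n_excl = int(scores["excluded"].sum())
    print(f"{n} parcels scored; {n_excl} ({100 * n_excl / n:.1f}%) built after "
          f"1978 and excluded (score 0); {len(rejects)} rejected rows")
    active = scores.loc[~scores["excluded"], "final_score"]
    print("final-score distribution among pre-1979 parcels:")
    print(active.describe().round(2).to_string())


if __name__ == "__main__":
    main()
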