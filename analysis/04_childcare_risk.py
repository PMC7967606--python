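#!/usr/bin/env python
"""Score childcare centers by half-mile buffered community lead risk.

Writes results/childcare_risk.csv and the program-type x priority
tabulation; prints the tabulation with its margins.
"""

from pathlib import Path

import pandas as pd

from leadhazard.childcare import score_centers, tabulate_by_type
from leadhazard.io import read_childcare

RESULTS = Path("results")


def main() -> None:
    scores = pd.read_csv(RESULTS / "parcel_scores.csv")
    centers = read_childcare(RESULTS / "synthetic" / "childcare.csv")

    risks = score_centers(centers, scores, radius=0.5)
    risks.to_csv(RESULTS / "childcare_risk.csv", index=False)
    tab = tabulate_by_type(risks)
    tab.to_csv(RESULTS / "childcare_by_type.csv")

    n_nodata = int((risks["priority"] == "No Data").sum())
    print(f"{len(risks)} centers scored ({n_nodata} with empty buffers)")
    print("centers by program type and community-risk priority:")
    print(tab.to_string())


if __name__ == "__main__":
    main()
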