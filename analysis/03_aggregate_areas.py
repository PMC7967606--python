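#!/usr/bin/env python
"""Aggregate parcel scores to blocks, block groups, and tracts.

Writes results/area_scores_<level>.csv, choropleth GeoJSON per level,
and the category-by-level count table. Prints the count table -- the
synthetic county's analogue of the published quintile-classification
summary.
"""

from pathlib import Path

import pandas as pd

from leadhazard.areas import LEVELS, aggregate, category_counts
from leadhazard.io import read_children, read_geographies, write_area_geojson

RESULTS = Path("results")


def main() -> None:
    scores = pd.read_csv(RESULTS / "parcel_scores.csv")
    geos = read_geographies(RESULTS / "synthetic" / "geographies.geojson")
    children = read_children(RESULTS / "synthetic" / "children.csv")

    all_areas = []
    for level in LEVELS:
        child_ids = None
        if level in set(children["level"]):
            child_ids = children.loc[children["level"] == level, "geo_id"]
        area = aggregate(
            scores, level,
            known_geo_ids=geos.level(level)["geo_id"],
            child_geo_ids=child_ids,
        )
        area.to_csv(RESULTS / f"area_scores_{level}.csv", index=False)
        write_area_geojson(area, geos, level, RESULTS / f"area_scores_{level}.geojson")
        all_areas.append(area)

    counts = category_counts(pd.concat(all_areas))
    counts.to_csv(RESULTS / "category_counts.csv")
    print("units per risk category and level:")
    print(counts.to_string())


if __name__ == "__main__":
    main()
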