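import numpy as np
import pandas as pd
import pytest

from leadhazard.areas import aggregate
from leadhazard.scoring import score_table
from leadhazard.synthetic import SyntheticConfig, generate_county

# The ten worked example properties: (year, value, grade) and their
# published age score, value score, cumulative score, and final score.
# Property 1 is post-ban and excluded.
TABLE1 = [
    ("Property 1", 1985, 156_000, "C", None, None, None, 0.0, True),
    ("Property 2", 1971, 275_000, "B", 1, 1, 2, 0.2, False),
    ("Property 3", 1965, 130_000, "C", 1, 2, 3, 1.5, False),
    ("Property 4", 1961, 70_000, "C-", 1, 3, 4, 2.4, False),
    ("Property 5", 1955, 270_000, "B-", 2, 1, 3, 0.6, False),
    ("Property 6", 1951, 145_000, "C--", 2, 2, 4, 2.8, False),
    ("Property 7", 1943, 60_000, "D+", 2, 3, 5, 4.5, False),
    ("Property 8", 1932, 265_000, "A-", 3, 1, 4, 0.1, False),
    ("Property 9", 1927, 130_000, "C++", 3, 2, 5, 1.5, False),
    ("Property 10", 1910, 50_000, "D", 3, 3, 6, 6.0, False),
]


@pytest.fixture(scope="session")
def table1_parcels() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parcel_id": pid, "year_built": y, "appraised_value": v, "grade": g}
            for pid, y, v, g, *_ in TABLE1
        ]
    )


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def county(default_config):
    """One seeded realization of the default synthetic county."""
    return generate_county(default_config)


@pytest.fixture(scope="session")
def county_scores(county):
    scores, rejects = score_table(county["parcels"])
    assert rejects.empty
    return scores


@pytest.fixture(scope="session")
def tract_areas(county, county_scores):
    kids = county["children"]
    return aggregate(
        county_scores,
        "tract",
        known_geo_ids=county["geographies"].tracts["geo_id"],
        child_geo_ids=kids.loc[kids["level"] == "tract", "geo_id"],
    )


@pytest.fixture(scope="session")
def tract_children(county):
    kids = county["children"]
    return kids[kids["level"] == "tract"].reset_index(drop=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
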