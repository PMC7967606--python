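"""Readers and writers for the pipeline's file formats.

All tables are UTF-8 CSV with a header row; coordinates everywhere are
planar miles (no CRS transformation is performed — real auditor or TIGER
inputs must be pre-projected). Geographies travel as a single RFC 7946
FeatureCollection whose features carry ``id``, ``level`` (block /
block_group / tract) and ``parent_id`` properties.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .scoring import normalize_grade
from .synthetic import GeographySet

__all__ = [
    "read_parcels",
    "read_children",
    "read_childcare",
    "read_opportunity",
    "write_geographies",
    "read_geographies",
    "write_area_geojson",
    "input_digest",
]

_CURRENCY_RE = re.compile(r"[$,\s]")

PARCEL_COLUMNS = (
    "parcel_id", "year_built", "appraised_value", "grade",
    "x", "y", "block_id", "block_group_id", "tract_id",
)


def parse_currency(value) -> float:
    """Parse a money field, tolerating '$1,234'-style formatting."""
    if isinstance(value, str):
        value = _CURRENCY_RE.sub("", value)
    return float(value)


def read_parcels(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a parcel CSV; malformed rows go to a rejects frame.

    Column order is immaterial; a missing mandatory column is fatal.
    Returns (parcels, rejects) where rejects carries the 0-based data
    row number and a reason.
    """
    df = pd.read_csv(path, dtype={"parcel_id": str})
    mandatory = {"parcel_id", "year_built", "appraised_value", "grade"}
    missing = sorted(mandatory - set(df.columns))
    if missing:
        raise ValueError(f"parcel file {path} is missing mandatory columns: {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    year = pd.to_numeric(df["year_built"], errors="coerce")
    reasons[year.isna()] = "unparseable year_built"

    def _try_currency(v):
        try:
            return parse_currency(v)
        except (TypeError, ValueError):
            return np.nan

    value = df["appraised_value"].map(_try_currency)
    reasons[(reasons == "") & value.isna()] = "unparseable appraised_value"

    rejected = reasons != ""
    rejects = pd.DataFrame(
        {"row": np.flatnonzero(rejected.to_numpy()), "reason": reasons[rejected].to_numpy()}
    )
    out = df.loc[~rejected].copy()
    out["year_built"] = year[~rejected].astype(int)
    out["appraised_value"] = value[~rejected].astype(float)
    out["grade"] = out["grade"].astype(str).map(normalize_grade)
    return out.reset_index(drop=True), rejects


def read_children(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"geo_id": str, "level": str})
    for col in ("geo_id", "level", "under5_total"):
        if col not in df.columns:
            raise ValueError(f"children file {path} is missing mandatory column: {col!r}")
    return df


def read_childcare(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"center_id": str, "program_type": str})
    for col in ("center_id", "program_type", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"childcare file {path} is missing mandatory column: {col!r}")
    return df


def read_opportunity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    if "tract_id" not in df.columns:
        raise ValueError(f"opportunity file {path} is missing mandatory column: 'tract_id'")
    return df


def write_geographies(geos: GeographySet, path: str | Path) -> None:
    """Write all three levels as one GeoJSON FeatureCollection."""
    features = []
    for level in ("block", "block_group", "tract"):
        for rec in geos.level(level).itertuples(index=False):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(rec.geometry),
                    "properties": {
                        "id": rec.geo_id,
                        "level": level,
                        "parent_id": rec.parent_id,
                    },
                }
            )
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "metadata": {"coordinate_units": "miles", "crs": "planar"},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_geographies(path: str | Path) -> GeographySet:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    frames: dict[str, list] = {"block": [], "block_group": [], "tract": []}
    for feat in payload["features"]:
        props = feat["properties"]
        frames[props["level"]].append(
            {
                "geo_id": props["id"],
                "parent_id": props["parent_id"],
                "geometry": shape(feat["geometry"]),
            }
        )
    dfs = {lvl: pd.DataFrame.from_records(rows) for lvl, rows in frames.items()}
    xs, ys = [], []
    for g in dfs["block"]["geometry"]:
        x0, y0, x1, y1 = g.bounds
        xs += [x0, x1]
        ys += [y0, y1]
    return GeographySet(
        blocks=dfs["block"],
        block_groups=dfs["block_group"],
        tracts=dfs["tract"],
        county_bounds=(min(xs), min(ys), max(xs), max(ys)),
    )


def write_area_geojson(
    areas: pd.DataFrame, geos: GeographySet, level: str, path: str | Path
) -> None:
    """Plain choropleth export: level polygons joined to risk categories."""
    geom = geos.level(level).set_index("geo_id")["geometry"]
    features = []
    for rec in areas.itertuples(index=False):
        if rec.geo_id not in geom.index:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom.loc[rec.geo_id]),
                "properties": {
                    "id": rec.geo_id,
                    "level": level,
                    "mean_score": None if pd.isna(rec.mean_score) else float(rec.mean_score),
                    "category": rec.category,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}), encoding="utf-8"
    )


def input_digest(path: str | Path) -> str:
    """SHA-256 of a file, for the run manifest."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
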