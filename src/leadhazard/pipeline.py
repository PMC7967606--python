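"""End-to-end pipeline: simulate -> score -> aggregate -> childcare -> equity.

Each stage reads/writes the package's standard file schemas under one
output directory and a ``manifest.json`` records input digests, the
configuration, the seed, and the package version, so that an identical
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .areas import LEVELS, aggregate, category_counts
from .childcare import DEFAULT_RADIUS_MILES, score_centers, tabulate_by_type
from .equity import (
    exposure_table,
    nonwhite_crosstab,
    opportunity_association,
    race_risk_distribution,
    risk_race_association,
)
from .io import (
    input_digest,
    read_childcare,
    read_children,
    read_geographies,
    read_opportunity,
    read_parcels,
    write_area_geojson,
    write_geographies,
)
from .scoring import GradeModifierTable, TierRules, default_modifiers, score_table
from .synthetic import SyntheticConfig, generate_county

log = logging.getLogger("leadhazard")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "simulate_to_dir"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    When ``simulate`` is true the five inputs are generated into
    ``out_dir/inputs`` from ``synthetic`` + ``seed``; otherwise the
    explicit input paths must exist.
    """

    out_dir: Path
    simulate: bool = True
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    parcels_path: Path | None = None
    geographies_path: Path | None = None
    children_path: Path | None = None
    childcare_path: Path | None = None
    opportunity_path: Path | None = None
    tier_rules: TierRules = field(default_factory=TierRules)
    modifiers: GradeModifierTable = field(default_factory=default_modifiers)
    buffer_radius: float = DEFAULT_RADIUS_MILES
    write_geojson: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        kwargs: dict = {"out_dir": Path(raw["out_dir"])}
        for key in ("simulate", "seed", "buffer_radius", "write_geojson"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in (
            "parcels_path", "geographies_path", "children_path",
            "childcare_path", "opportunity_path",
        ):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["synthetic"].items()
            })
        if "tier_rules" in raw:
            kwargs["tier_rules"] = TierRules(**raw["tier_rules"])
        if "modifiers" in raw:
            kwargs["modifiers"] = GradeModifierTable(modifiers=raw["modifiers"])
        return cls(**kwargs)


def _csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def simulate_to_dir(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the synthetic county and write its five input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    county = generate_county(config)
    paths = {
        "parcels": out / "parcels.csv",
        "geographies": out / "geographies.geojson",
        "children": out / "children.csv",
        "childcare": out / "childcare.csv",
        "opportunity": out / "opportunity.csv",
    }
    _csv(county["parcels"], paths["parcels"])
    write_geographies(county["geographies"], paths["geographies"])
    _csv(county["children"], paths["children"])
    _csv(county["childcare"], paths["childcare"])
    _csv(county["opportunity"], paths["opportunity"])
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    try:
        if config.simulate:
            syn = config.synthetic.with_seed(config.seed)
            inputs = simulate_to_dir(syn, out / "inputs")
        else:
            inputs = {
                "parcels": config.parcels_path,
                "geographies": config.geographies_path,
                "children": config.children_path,
                "childcare": config.childcare_path,
                "opportunity": config.opportunity_path,
            }
            for name, p in inputs.items():
                if name in ("parcels",) and p is None:
                    raise FileNotFoundError(f"no {name} file configured")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # -- score -------------------------------------------------------------
    try:
        parcels, read_rejects = read_parcels(inputs["parcels"])
        log.info("score: read %d parcels (%d rejected on read)", len(parcels), len(read_rejects))
        scores, score_rejects = score_table(parcels, config.tier_rules, config.modifiers)
        rejects = pd.concat([read_rejects, score_rejects], ignore_index=True)
        log.info(
            "score: %d scored, %d excluded (post-%d), %d rejected",
            len(scores), int(scores["excluded"].sum()),
            config.tier_rules.exclusion_after, len(rejects),
        )
        _csv(
            scores[
                ["parcel_id", "excluded", "age_score", "value_score",
                 "cumulative", "modifier", "final_score"]
            ],
            out / "parcel_scores.csv",
        )
        _csv(rejects, out / "rejects.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("score", e) from e

    # -- aggregate ---------------------------------------------------------
    try:
        geos = read_geographies(inputs["geographies"]) if inputs.get("geographies") else None
        children = read_children(inputs["children"]) if inputs.get("children") else None
        areas = {}
        for level in LEVELS:
            if f"{level}_id" not in scores.columns:
                log.info("aggregate: no %s_id column, level skipped", level)
                continue
            known = geos.level(level)["geo_id"] if geos is not None else None
            child_ids = None
            if children is not None and level in set(children["level"]):
                child_ids = children.loc[children["level"] == level, "geo_id"]
            area = aggregate(scores, level, known_geo_ids=known, child_geo_ids=child_ids)
            areas[level] = area
            _csv(area, out / f"area_scores_{level}.csv")
            if config.write_geojson and geos is not None:
                write_area_geojson(area, geos, level, out / f"area_scores_{level}.geojson")
        if areas:
            category_counts(pd.concat(areas.values())).to_csv(out / "category_counts.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("aggregate", e) from e

    # -- childcare ---------------------------------------------------------
    try:
        if inputs.get("childcare") and {"x", "y"} <= set(scores.columns):
            centers = read_childcare(inputs["childcare"])
            if geos is not None:
                x0, y0, x1, y1 = geos.county_bounds
                in_bounds = centers["x"].between(x0, x1) & centers["y"].between(y0, y1)
                if (~in_bounds).any():
                    log.info("childcare: %d centers outside county bounds excluded",
                             int((~in_bounds).sum()))
                centers = centers[in_bounds]
            risks = score_centers(centers, scores, radius=config.buffer_radius)
            _csv(risks, out / "childcare_risk.csv")
            tabulate_by_type(risks).to_csv(out / "childcare_by_type.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("childcare", e) from e

    # -- equity ------------------------------------------------------------
    try:
        if children is not None and "tract" in areas:
            tract_children = children[children["level"] == "tract"]
            tract_areas = areas["tract"]
            table, meta = exposure_table(tract_areas, tract_children)
            table.to_csv(out / "exposure_table.csv")
            (out / "exposure_meta.json").write_text(json.dumps(meta, indent=2))
            counts, summary = race_risk_distribution(tract_areas, tract_children)
            counts.to_csv(out / "race_risk.csv")
            summary.to_csv(out / "race_risk_summary.csv")
            crosstab, ct_meta = nonwhite_crosstab(tract_areas, tract_children)
            crosstab.to_csv(out / "nonwhite_crosstab.csv")
            rho, p = risk_race_association(tract_areas, tract_children)
            equity_meta = {"crosstab": ct_meta, "spearman_rho": rho, "spearman_p": p}
            if inputs.get("opportunity"):
                opp = read_opportunity(inputs["opportunity"])
                fits = opportunity_association(tract_areas, opp)
                (out / "opportunity_fit.json").write_text(
                    json.dumps([dataclasses.asdict(f) for f in fits], indent=2)
                )
            (out / "equity_meta.json").write_text(json.dumps(equity_meta, indent=2))
    except Exception as e:  # noqa: BLE001
        raise StageError("equity", e) from e

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "simulate": config.simulate,
        "buffer_radius": config.buffer_radius,
        "tier_rules": dataclasses.asdict(config.tier_rules),
        "modifier_provenance": config.modifiers.provenance,
        "inputs": {
            name: {"path": str(p), "sha256": input_digest(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    if config.simulate:
        syn = dataclasses.asdict(config.synthetic.with_seed(config.seed))
        syn["grade_distribution"] = {k: list(v) for k, v in syn["grade_distribution"].items()}
        manifest["synthetic"] = syn
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
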