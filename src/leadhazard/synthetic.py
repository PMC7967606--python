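"""Synthetic county generator.

Produces a complete, self-consistent county — square-grid census
geographies, residential parcels, child population by race, childcare
centers, and tract opportunity indices — with the statistical structure
the hazard analysis assumes: older, cheaper, lower-grade housing
concentrates toward the county center; the non-white share of young
children rises with tract housing age; childcare centers cluster
centrally; and opportunity indices decline linearly with tract risk plus
calibrated noise.

Every generator is a pure function of (config, seed): the master seed
fans out to named, independent substreams so adding a generator never
perturbs the draws of an existing one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import box
from shapely.ops import unary_union

from .childcare import PROGRAM_TYPES
from .scoring import GRADE_SCALE

__all__ = [
    "BLOCK_SIZE_MILES",
    "SyntheticConfig",
    "GeographySet",
    "generate_geographies",
    "generate_parcels",
    "generate_children",
    "generate_childcare",
    "generate_opportunity",
    "generate_county",
]

#: Side length of a square census block, miles.
BLOCK_SIZE_MILES = 0.5

# Fixed substream keys: append-only, never reorder.
_SUBSTREAMS = {"parcels": 0, "children": 1, "childcare": 2, "opportunity": 3}

# Steepness of the post-1978 probability in the centrality covariate.
# Steep enough that outer-edge blocks are near-wholly post-ban suburbs
# while the urban core is near-wholly pre-ban housing.
_POST1978_SLOPE = 9.0

# SD of the per-block development-cohort effect on the same log-odds scale.
_BLOCK_COHORT_SD = 2.5

# Value-tier conditional grade mix (worst -> best over GRADE_SCALE).
# Cheap housing skews toward D/C- grades, expensive toward B/A.
_DEFAULT_GRADE_WEIGHTS = {
    "low": [2, 3, 6, 16, 12, 14, 15, 17, 7, 4, 2, 1, 0.5, 0.3, 0.1, 0.06, 0.04],
    "moderate": [0.2, 0.4, 1, 4, 5, 8, 12, 30, 14, 10, 7, 5, 2, 0.8, 0.4, 0.1, 0.1],
    "high": [0.05, 0.05, 0.1, 0.3, 0.5, 1, 2, 8, 8, 12, 18, 20, 12, 8, 6, 2.5, 1.5],
}

# Program-type marginal mix for generated childcare centers (published
# county composition; Licensed Childcare Center is modal).
_PROGRAM_TYPE_COUNTS = (2, 636, 3, 216, 129, 69, 20)


def _default_grade_distribution() -> dict[str, tuple[float, ...]]:
    out = {}
    for tier, w in _DEFAULT_GRADE_WEIGHTS.items():
        a = np.asarray(w, dtype=float)
        out[tier] = tuple(a / a.sum())
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic county.

    Defaults emulate the published study conditions at desk scale: a
    10 x 10 mile county of 400 half-mile blocks (100 block groups, 50
    tracts), 20,000 residential parcels of which 47.4% post-date the
    1978 lead-paint ban, and opportunity indices calibrated to R^2 of
    0.62 (COI) and 0.53 (HOI) against tract risk.
    """

    n_parcels: int = 20_000
    grid_blocks: tuple[int, int] = (20, 20)
    blocks_per_block_group: int = 4
    block_groups_per_tract: int = 2
    frac_post1978: float = 0.474
    #: Length scale (miles) of the centrality covariate exp(-d/decay);
    #: infinity removes every spatial gradient.
    center_decay: float = 4.0
    #: (mu, sigma) of log appraised value before the spatial shift.
    value_lognormal_params: tuple[float, float] = (math.log(140_000.0), 0.55)
    grade_distribution: dict[str, tuple[float, ...]] = field(
        default_factory=_default_grade_distribution
    )
    n_centers: int = 150
    #: Log-odds increase of tract non-white under-5 share per SD of
    #: tract mean housing age; 0 decouples race from risk.
    race_gradient: float = 1.5
    #: Residual SD for COI/HOI; None calibrates from the target R^2.
    opp_index_noise_sd: float | None = None
    opp_target_r2: dict[str, float] = field(
        default_factory=lambda: {"coi": 0.62, "hoi": 0.53}
    )
    #: Mean under-5 children per block group (Poisson).
    mean_under5_per_block_group: float = 60.0
    #: Expected additional 5-17-year-olds per under-5 child.
    under18_multiplier: float = 2.3
    #: Baseline county-wide non-white under-5 share.
    baseline_nonwhite_share: float = 0.35
    #: Conditional split of the non-white share across races.
    nonwhite_mix: dict[str, float] = field(
        default_factory=lambda: {"Black": 0.65, "Hispanic": 0.20, "Asian": 0.08, "Other": 0.07}
    )
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_blocks
        if rows < 2 or cols < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.grid_blocks}")
        if self.n_parcels < 1:
            raise ValueError("n_parcels must be >= 1")
        if not 0.0 <= self.frac_post1978 <= 1.0:
            raise ValueError("frac_post1978 must lie in [0, 1]")
        if not 0.0 < self.baseline_nonwhite_share < 1.0:
            raise ValueError("baseline_nonwhite_share must lie in (0, 1)")
        if self.center_decay <= 0:
            raise ValueError("center_decay must be positive (may be inf)")
        n_blocks = rows * cols
        if self.blocks_per_block_group < 1 or n_blocks < self.blocks_per_block_group:
            raise ValueError("grid smaller than one block group")
        if n_blocks % self.blocks_per_block_group:
            raise ValueError("block count must divide evenly into block groups")
        n_bg = n_blocks // self.blocks_per_block_group
        if self.block_groups_per_tract < 1 or n_bg % self.block_groups_per_tract:
            raise ValueError("block groups must divide evenly into tracts")
        for tier, probs in self.grade_distribution.items():
            p = np.asarray(probs, dtype=float)
            if len(p) != len(GRADE_SCALE):
                raise ValueError(
                    f"grade_distribution[{tier!r}] must have {len(GRADE_SCALE)} entries"
                )
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"grade_distribution[{tier!r}] must sum to 1")
        mix = sum(self.nonwhite_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("nonwhite_mix must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator."""
        key = _SUBSTREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key,))
        )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GeographySet:
    """Nested square-grid census geographies in planar mile coordinates.

    Each level is a DataFrame with ``geo_id``, ``parent_id`` and a
    shapely ``geometry`` column; blocks tile the county rectangle.
    """

    blocks: pd.DataFrame
    block_groups: pd.DataFrame
    tracts: pd.DataFrame
    county_bounds: tuple[float, float, float, float]

    def level(self, name: str) -> pd.DataFrame:
        return {"block": self.blocks, "block_group": self.block_groups, "tract": self.tracts}[name]

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.county_bounds
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def generate_geographies(config: SyntheticConfig) -> GeographySet:
    """Deterministically build the nested block / block-group / tract grid.

    Blocks are ``BLOCK_SIZE_MILES`` squares in row-major order, grouped
    into block groups by consecutive runs and block groups into tracts
    the same way.
    """
    config.validate()
    rows, cols = config.grid_blocks
    s = BLOCK_SIZE_MILES
    records = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            bg = i // config.blocks_per_block_group
            tract = bg // config.block_groups_per_tract
            records.append(
                {
                    "geo_id": f"B{i:05d}",
                    "parent_id": f"G{bg:04d}",
                    "tract_id": f"T{tract:03d}",
                    "geometry": box(c * s, r * s, (c + 1) * s, (r + 1) * s),
                }
            )
    blocks = pd.DataFrame.from_records(records)

    bg_records = []
    for bg_id, grp in blocks.groupby("parent_id", sort=True):
        bg_records.append(
            {
                "geo_id": bg_id,
                "parent_id": grp["tract_id"].iloc[0],
                "geometry": unary_union(list(grp["geometry"])),
            }
        )
    block_groups = pd.DataFrame.from_records(bg_records)

    tract_records = []
    for t_id, grp in block_groups.groupby("parent_id", sort=True):
        tract_records.append(
            {
                "geo_id": t_id,
                "parent_id": None,
                "geometry": unary_union(list(grp["geometry"])),
            }
        )
    tracts = pd.DataFrame.from_records(tract_records)
    return GeographySet(
        blocks=blocks.drop(columns="tract_id"),
        block_groups=block_groups,
        tracts=tracts,
        county_bounds=(0.0, 0.0, cols * s, rows * s),
    )


def _centrality(config: SyntheticConfig, x: np.ndarray, y: np.ndarray,
                center: tuple[float, float]) -> np.ndarray:
    """exp(-distance/decay): 1 at the county center, falling outward."""
    d = np.hypot(x - center[0], y - center[1])
    if math.isinf(config.center_decay):
        return np.ones_like(d)
    return np.exp(-d / config.center_decay)


def _calibrate_post1978(eta: np.ndarray, target: float) -> np.ndarray:
    """Per-parcel post-1978 probabilities: logistic in the linear
    predictor ``eta``, with the intercept solved so the mean equals
    ``target``."""
    if target <= 0.0:
        return np.zeros_like(eta)
    if target >= 1.0:
        return np.ones_like(eta)

    def mean_p(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + eta))))) - target

    a = brentq(mean_p, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-(a + eta)))


def generate_parcels(config: SyntheticConfig, geographies: GeographySet) -> pd.DataFrame:
    """Draw the residential parcel table.

    Parcels are placed uniformly over blocks; year built and appraised
    value shift with the centrality covariate so central housing is
    older and cheaper; grade is drawn conditional on the value tier.
    """
    config.validate()
    rng = config.rng("parcels")
    n = config.n_parcels
    blocks = geographies.blocks
    n_blocks = len(blocks)

    block_idx = rng.integers(0, n_blocks, size=n)
    bounds = np.array([g.bounds for g in blocks["geometry"]])
    bx0, by0 = bounds[block_idx, 0], bounds[block_idx, 1]
    x = bx0 + rng.random(n) * BLOCK_SIZE_MILES
    y = by0 + rng.random(n) * BLOCK_SIZE_MILES

    g = _centrality(config, x, y, geographies.center)

    # Housing in a block is built as a cohort: a per-block random effect
    # on the development-era predictor makes wholly post-ban subdivision
    # blocks (and wholly pre-ban core blocks) realistically common.
    block_effect = rng.normal(0.0, _BLOCK_COHORT_SD, size=n_blocks)
    eta = -_POST1978_SLOPE * g + block_effect[block_idx]
    p_post = _calibrate_post1978(eta, config.frac_post1978)
    is_post = rng.random(n) < p_post
    year = np.empty(n, dtype=int)
    year[is_post] = 1979 + rng.integers(0, 42, size=int(is_post.sum()))
    n_pre = int((~is_post).sum())
    pre_mean = 1972.0 - 48.0 * g[~is_post]
    year[~is_post] = np.clip(
        np.rint(pre_mean + rng.normal(0.0, 12.0, size=n_pre)), 1875, 1978
    ).astype(int)

    mu, sigma = config.value_lognormal_params
    value = np.exp(mu + 1.0 * (0.5 - g) + sigma * rng.normal(size=n))
    value = np.round(value, -2)  # appraisals come in round hundreds

    tier = np.select([value < 100_000, value <= 200_000], ["low", "moderate"], "high")
    grade = np.empty(n, dtype=object)
    grades = np.array(GRADE_SCALE, dtype=object)
    for t in ("low", "moderate", "high"):
        mask = tier == t
        k = int(mask.sum())
        if k:
            grade[mask] = rng.choice(grades, size=k, p=config.grade_distribution[t])

    return pd.DataFrame(
        {
            "parcel_id": [f"P{i:06d}" for i in range(n)],
            "year_built": year,
            "appraised_value": value,
            "grade": grade,
            "x": x,
            "y": y,
            "block_id": blocks["geo_id"].to_numpy()[block_idx],
            "block_group_id": blocks["parent_id"].to_numpy()[block_idx],
            "tract_id": blocks["parent_id"].map(
                geographies.block_groups.set_index("geo_id")["parent_id"]
            ).to_numpy()[block_idx],
        }
    )


def generate_children(
    config: SyntheticConfig, geographies: GeographySet, parcels: pd.DataFrame
) -> pd.DataFrame:
    """Draw the child-population table.

    Block-group rows carry under-5 totals only (mirroring the block-group
    age table of the census product emulated here); tract rows carry
    under-5 and under-18 totals plus the under-5 race decomposition. The
    non-white share per tract follows a logistic curve in standardised
    tract mean housing age with slope ``race_gradient``.
    """
    config.validate()
    rng = config.rng("children")
    bgs = geographies.block_groups

    u5_bg = rng.poisson(config.mean_under5_per_block_group, size=len(bgs))
    extra_bg = rng.poisson(config.under18_multiplier * u5_bg)
    u18_bg = u5_bg + extra_bg

    bg_rows = pd.DataFrame(
        {
            "geo_id": bgs["geo_id"],
            "level": "block_group",
            "under5_total": u5_bg,
            "under18_total": np.nan,
        }
    )

    tract_of_bg = bgs.set_index("geo_id")["parent_id"]
    tmp = pd.DataFrame(
        {"tract_id": tract_of_bg.loc[bgs["geo_id"]].to_numpy(), "u5": u5_bg, "u18": u18_bg}
    )
    per_tract = tmp.groupby("tract_id", sort=True).sum()

    mean_year = parcels.groupby("tract_id")["year_built"].mean()
    mean_year = mean_year.reindex(per_tract.index)
    mean_year = mean_year.fillna(mean_year.mean())
    age = -mean_year.to_numpy(dtype=float)  # older housing -> larger
    sd = age.std()
    z = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    logit0 = math.log(config.baseline_nonwhite_share / (1 - config.baseline_nonwhite_share))
    s = 1.0 / (1.0 + np.exp(-(logit0 + config.race_gradient * z)))

    mix = config.nonwhite_mix
    probs = np.column_stack(
        [1.0 - s] + [s * mix[r] for r in ("Black", "Asian", "Hispanic", "Other")]
    )
    counts = np.vstack(
        [rng.multinomial(int(t), p) for t, p in zip(per_tract["u5"], probs)]
    )
    tract_rows = pd.DataFrame(
        {
            "geo_id": per_tract.index,
            "level": "tract",
            "under5_total": per_tract["u5"].to_numpy(),
            "under18_total": per_tract["u18"].to_numpy(),
            "under5_white": counts[:, 0],
            "under5_black": counts[:, 1],
            "under5_asian": counts[:, 2],
            "under5_hispanic": counts[:, 3],
            "under5_other": counts[:, 4],
        }
    )
    return pd.concat([bg_rows, tract_rows], ignore_index=True)


def generate_childcare(config: SyntheticConfig, geographies: GeographySet) -> pd.DataFrame:
    """Draw childcare centers: positions weighted toward the county
    center, program types from the published county marginal mix."""
    config.validate()
    rng = config.rng("childcare")
    n = config.n_centers
    if n == 0:
        return pd.DataFrame(columns=["center_id", "program_type", "x", "y"])
    blocks = geographies.blocks
    cent = np.array([g.centroid.coords[0] for g in blocks["geometry"]])
    w = _centrality(config, cent[:, 0], cent[:, 1], geographies.center)
    w = w / w.sum()
    idx = rng.choice(len(blocks), size=n, p=w)
    bounds = np.array([g.bounds for g in blocks["geometry"]])
    x = bounds[idx, 0] + rng.random(n) * BLOCK_SIZE_MILES
    y = bounds[idx, 1] + rng.random(n) * BLOCK_SIZE_MILES
    type_p = np.asarray(_PROGRAM_TYPE_COUNTS, dtype=float)
    type_p /= type_p.sum()
    types = rng.choice(np.array(PROGRAM_TYPES, dtype=object), size=n, p=type_p)
    return pd.DataFrame(
        {
            "center_id": [f"CC{i:04d}" for i in range(n)],
            "program_type": types,
            "x": x,
            "y": y,
        }
    )


def generate_opportunity(
    config: SyntheticConfig, tract_scores: pd.DataFrame
) -> pd.DataFrame:
    """Generate tract COI/HOI as negative linear functions of risk.

    The residual SD is either ``opp_index_noise_sd`` or, by default,
    calibrated per index from the closed form
    ``sd = |slope| * sd(score) * sqrt(1/R^2 - 1)`` so the expected
    regression R^2 equals the configured target.
    """
    config.validate()
    if len(tract_scores) < 3:
        raise ValueError("need at least 3 tracts to generate opportunity indices")
    rng = config.rng("opportunity")
    score = tract_scores["mean_score"].to_numpy(dtype=float)
    sd_score = score.std(ddof=1)
    params = {"coi": (80.0, -12.0), "hoi": (75.0, -12.0)}
    out = {"tract_id": tract_scores["geo_id"].to_numpy()}
    for name, (intercept, slope) in params.items():
        if config.opp_index_noise_sd is not None:
            sd_noise = float(config.opp_index_noise_sd)
        else:
            r2 = config.opp_target_r2[name]
            sd_noise = abs(slope) * sd_score * math.sqrt(1.0 / r2 - 1.0)
        out[name] = intercept + slope * score + rng.normal(0.0, sd_noise, size=len(score))
    return pd.DataFrame(out)


def generate_county(config: SyntheticConfig) -> dict:
    """Run every generator; returns a dict of the five input tables plus
    the geography set. Opportunity indices are generated against
    provisional tract mean *final* scores computed from the parcels."""
    from .areas import aggregate
    from .scoring import score_table

    geos = generate_geographies(config)
    parcels = generate_parcels(config, geos)
    children = generate_children(config, geos, parcels)
    centers = generate_childcare(config, geos)
    scores, _ = score_table(parcels)
    tract_scores = aggregate(scores, "tract", known_geo_ids=geos.tracts["geo_id"])
    opportunity = generate_opportunity(config, tract_scores)
    return {
        "geographies": geos,
        "parcels": parcels,
        "children": children,
        "childcare": centers,
        "opportunity": opportunity,
    }
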