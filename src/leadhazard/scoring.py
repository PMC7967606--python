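"""Per-parcel lead-paint hazard scoring.

A residential parcel built in 1978 or earlier receives an age-tier score
(pre-1940 housing is the most likely to carry lead paint), a value-tier
score (low appraised value proxies disinvestment and deferred maintenance),
and their sum -- the cumulative score in {2..6} -- is multiplied by a
grade-quality modifier reflecting the appraiser's construction/condition
grade. Parcels built after 1978, when residential lead paint was banned,
are excluded and carry a final score of 0 so that neighborhood means still
count them in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "GRADE_SCALE",
    "TierRules",
    "GradeModifierTable",
    "ParcelScore",
    "default_modifiers",
    "normalize_grade",
    "score_age",
    "score_value",
    "score_parcel",
    "score_table",
]


class _Excluded:
    """Sentinel for parcels outside the hazard window (built after 1978)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EXCLUDED"


EXCLUDED = _Excluded()

#: Auditor construction-quality grades, worst to best.  E-- marks visible
#: disrepair; A++ is custom, high-end construction.
GRADE_SCALE: tuple[str, ...] = (
    "E--", "E-", "E",
    "D", "D+",
    "C--", "C-", "C", "C+", "C++",
    "B-", "B", "B+",
    "A-", "A", "A+", "A++",
)

_GRADE_RANK = {g: i for i, g in enumerate(GRADE_SCALE)}

# Default modifiers.  Nine grades are anchored exactly by the worked
# scoring examples (final score / cumulative score); the remaining grades
# are completed monotonically and can be overridden via configuration.
_ANCHORED_MODIFIERS = {
    "D": 1.0, "D+": 0.9,
    "C--": 0.7, "C-": 0.6, "C": 0.5, "C++": 0.3,
    "B-": 0.2, "B": 0.1,
    "A-": 0.025,
}
_COMPLETED_MODIFIERS = {
    "E--": 1.3, "E-": 1.2, "E": 1.1,
    "C+": 0.4,
    "B+": 0.05,
    "A": 0.02, "A+": 0.015, "A++": 0.01,
}


def normalize_grade(grade: str) -> str:
    """Canonicalise a grade label: strip whitespace, uppercase, and map
    Unicode minus/dash variants to the ASCII hyphen used internally."""
    return (
        str(grade).strip().upper()
        .replace("−", "-").replace("–", "-").replace("—", "-")
    )


@dataclass(frozen=True)
class TierRules:
    """Age and value tier boundaries.

    Age tiers: built before ``oldest_before`` scores 3, before
    ``newer_after`` scores 2, through ``exclusion_after`` scores 1, and
    anything newer is excluded. Value tiers: below ``value_low_below``
    scores 3, up to ``value_high_above`` (inclusive) scores 2, above it
    scores 1.
    """

    oldest_before: int = 1940
    newer_after: int = 1960
    exclusion_after: int = 1978
    value_low_below: float = 100_000.0
    value_high_above: float = 200_000.0

    def __post_init__(self) -> None:
        if not (self.oldest_before < self.newer_after < self.exclusion_after):
            raise ValueError(
                "age breaks must be strictly increasing: "
                f"{self.oldest_before}, {self.newer_after}, {self.exclusion_after}"
            )
        if not (0 < self.value_low_below < self.value_high_above):
            raise ValueError(
                "value breaks must be strictly increasing and positive: "
                f"{self.value_low_below}, {self.value_high_above}"
            )


@dataclass(frozen=True)
class GradeModifierTable:
    """Grade -> multiplicative risk modifier.

    Modifiers must be positive and non-increasing as grade quality
    improves (a D home never scores lower than an otherwise identical C
    home). ``provenance`` records whether the table is the package
    default or user-supplied.
    """

    modifiers: dict[str, float]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        clean = {normalize_grade(g): float(m) for g, m in self.modifiers.items()}
        object.__setattr__(self, "modifiers", clean)
        for g, m in clean.items():
            if not np.isfinite(m) or m <= 0:
                raise ValueError(f"modifier for grade {g!r} must be positive, got {m}")
        known = sorted(
            (g for g in clean if g in _GRADE_RANK), key=_GRADE_RANK.__getitem__
        )
        for worse, better in zip(known, known[1:]):
            if clean[worse] < clean[better]:
                raise ValueError(
                    "modifiers must be non-increasing as grade improves: "
                    f"{worse}={clean[worse]} < {better}={clean[better]}"
                )

    def lookup(self, grade: str) -> float:
        g = normalize_grade(grade)
        try:
            return self.modifiers[g]
        except KeyError:
            raise KeyError(
                f"grade {g!r} is not in the modifier table "
                f"(known: {', '.join(sorted(self.modifiers))})"
            ) from None

    def __contains__(self, grade: str) -> bool:
        return normalize_grade(grade) in self.modifiers


def default_modifiers() -> GradeModifierTable:
    """The package's default grade-modifier table.

    Nine grades (D, D+, C--, C-, C, C++, B-, B, A-) are fixed exactly by
    the published worked examples; the rest are a monotone completion.
    """
    return GradeModifierTable(
        modifiers={**_ANCHORED_MODIFIERS, **_COMPLETED_MODIFIERS},
        provenance="default-reconstructed",
    )


def score_age(year_built: int, rules: TierRules = TierRules()):
    """Age-tier score: 3 (oldest), 2, or 1; EXCLUDED for post-ban years."""
    y = int(year_built)
    if y > rules.exclusion_after:
        return EXCLUDED
    if y < rules.oldest_before:
        return 3
    if y < rules.newer_after:
        return 2
    return 1


def score_value(appraised_value: float, rules: TierRules = TierRules()) -> int:
    """Value-tier score: 3 (low), 2 (moderate, endpoints inclusive), 1 (high)."""
    v = float(appraised_value)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"appraised value must be a finite non-negative number, got {v}")
    if v < rules.value_low_below:
        return 3
    if v <= rules.value_high_above:
        return 2
    return 1


@dataclass(frozen=True)
class ParcelScore:
    parcel_id: str
    excluded: bool
    age_score: int | None = None
    value_score: int | None = None
    cumulative: int | None = None
    modifier: float | None = None
    final_score: float = 0.0


def score_parcel(
    parcel_id: str,
    year_built: int,
    appraised_value: float,
    grade: str,
    rules: TierRules = TierRules(),
    modifiers: GradeModifierTable | None = None,
) -> ParcelScore:
    """Score one parcel: (age tier + value tier) x grade modifier, or an
    excluded record with final score 0 for post-ban construction."""
    if modifiers is None:
        modifiers = default_modifiers()
    age = score_age(year_built, rules)
    if age is EXCLUDED:
        return ParcelScore(parcel_id=str(parcel_id), excluded=True, final_score=0.0)
    value = score_value(appraised_value, rules)
    mod = modifiers.lookup(grade)
    cumulative = age + value
    return ParcelScore(
        parcel_id=str(parcel_id),
        excluded=False,
        age_score=age,
        value_score=value,
        cumulative=cumulative,
        modifier=mod,
        final_score=cumulative * mod,
    )


def _vector_age_scores(years: pd.Series, rules: TierRules) -> np.ndarray:
    y = years.to_numpy()
    return np.select(
        [y > rules.exclusion_after, y < rules.oldest_before, y < rules.newer_after],
        [0, 3, 2],
        default=1,
    )


def _vector_value_scores(values: pd.Series, rules: TierRules) -> np.ndarray:
    v = values.to_numpy(dtype=float)
    return np.select(
        [v < rules.value_low_below, v <= rules.value_high_above], [3, 2], default=1
    )


def score_table(
    parcels: pd.DataFrame,
    rules: TierRules = TierRules(),
    modifiers: GradeModifierTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a parcel table; invalid rows go to a rejects report.

    Parameters
    ----------
    parcels
        DataFrame with at least ``parcel_id``, ``year_built``,
        ``appraised_value``, ``grade``. Extra columns (coordinates,
        geography ids) are carried through unchanged.

    Returns
    -------
    (scores, rejects)
        ``scores`` has one row per valid input parcel, in input order,
        with columns ``excluded, age_score, value_score, cumulative,
        modifier, final_score`` appended. ``rejects`` lists each dropped
        row with its positional index and a reason.
    """
    if modifiers is None:
        modifiers = default_modifiers()
    required = {"parcel_id", "year_built", "appraised_value", "grade"}
    missing = required - set(parcels.columns)
    if missing:
        raise ValueError(f"parcel table is missing columns: {sorted(missing)}")

    df = parcels.copy()
    reject_reason = pd.Series("", index=df.index, dtype=object)

    years = pd.to_numeric(df["year_built"], errors="coerce")
    bad_year = years.isna() | (years < 1850) | (years > 2100)
    reject_reason[bad_year & (reject_reason == "")] = "invalid year_built"

    values = pd.to_numeric(df["appraised_value"], errors="coerce")
    bad_value = values.isna() | (values < 0)
    reject_reason[bad_value & (reject_reason == "")] = "invalid appraised_value"

    grades = df["grade"].astype(str).map(normalize_grade)
    # Grade is only consulted for non-excluded parcels; a post-1978 parcel
    # with a malformed grade still scores 0 rather than being rejected.
    needs_grade = ~bad_year & (years <= rules.exclusion_after)
    bad_grade = needs_grade & ~grades.isin(list(modifiers.modifiers))
    unknown = sorted(grades[bad_grade].unique())
    if unknown:
        raise KeyError(
            f"grades not present in the modifier table: {unknown}"
        )

    rejected = reject_reason != ""
    rejects = pd.DataFrame(
        {"row": np.flatnonzero(rejected.to_numpy()), "reason": reject_reason[rejected].to_numpy()}
    )

    valid = df.loc[~rejected].copy()
    vy = years[~rejected]
    vv = values[~rejected]
    vg = grades[~rejected]

    age = _vector_age_scores(vy, rules)  # 0 encodes excluded
    excl = age == 0
    value_score = _vector_value_scores(vv, rules)
    mod = vg.map(modifiers.modifiers).to_numpy(dtype=float)

    valid["year_built"] = vy.astype(int)
    valid["appraised_value"] = vv.astype(float)
    valid["grade"] = vg
    valid["excluded"] = excl
    valid["age_score"] = np.where(excl, np.nan, age)
    valid["value_score"] = np.where(excl, np.nan, value_score)
    valid["cumulative"] = np.where(excl, np.nan, age + value_score)
    valid["modifier"] = np.where(excl, np.nan, mod)
    valid["final_score"] = np.where(excl, 0.0, (age + value_score) * mod)
    return valid.reset_index(drop=True), rejects
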