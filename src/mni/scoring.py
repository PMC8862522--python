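"""My Nutrition Index (MNI) scoring.

Each of 34 nutrients is scored in [0, 1] against the individual's resolved
reference range with a piecewise-linear profile: 0 at the rise anchor
(default 0 intake), rising linearly to 1 at the lower bound L, 1 across
[L, U], and for a finite upper bound U falling linearly back to 0 at
``fall_span * U``. One-sided ranges keep the score at 1 on their open side.
Energy is scored the same way against a symmetric band around the
Mifflin-St Jeor target (default +/-10%). The composite MNI is 100 times the
geometric mean of the per-nutrient scores after flooring each at a small
positive value (default 0.01) so that a single absent nutrient does not
annihilate the index.

Reference ranges stored as % of energy (AMDR-style macronutrient bands,
sugar, saturated fat) or g/kg body weight (protein) are converted to g/day
here, using the person's *target* energy so that the resolved ranges do not
depend on the reported diet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .energy import EnergyTarget, target_energy
from .reference import (
    MODIFIER_ORDER,
    ReferenceDataError,
    ReferenceLibrary,
    ReferenceRange,
    load_reference_library,
    resolve_reference_ranges,
)
from .types import DailyIntake, IndividualProfile

__all__ = [
    "ScoreShape",
    "MNIResult",
    "MNIScorer",
    "score_nutrient",
    "score_energy",
    "compute_mni",
    "score_cohort",
    "to_ten_point",
    "absolute_bounds",
    "aggregate_scores",
    "full_score_intake",
]

# kcal per gram used to convert %-of-energy bands to g/day (Atwater factors).
KCAL_PER_G = {
    "carbohydrate": 4.0,
    "sugar": 4.0,
    "protein": 4.0,
    "total_fat": 9.0,
    "saturated_fat": 9.0,
    "monounsaturated_fat": 9.0,
    "polyunsaturated_fat": 9.0,
}


@dataclass(frozen=True)
class ScoreShape:
    """Tunable shape of the per-nutrient score and aggregation.

    rise_anchor
        Intake at which the score starts from 0 below the range (default 0).
    fall_span
        Multiple of the upper bound U at which the score reaches 0 above the
        range (default 2.0, i.e. zero at twice the upper bound).
    floor
        Minimum per-nutrient score entering the geometric mean (default 0.01).
    energy_band
        Half-width of the full-score energy band as a fraction of the target
        (default 0.10 for [0.9, 1.1] x target).
    protein_energy_cap_pct
        Upper bound for protein expressed as % of target energy (the
        macronutrient-distribution cap, default 35), applied when the g/kg
        protein range is converted to g/day.
    """

    rise_anchor: float = 0.0
    fall_span: float = 2.0
    floor: float = 0.01
    energy_band: float = 0.10
    protein_energy_cap_pct: float = 35.0

    def __post_init__(self) -> None:
        if self.fall_span <= 1:
            raise ValueError("fall_span must be > 1")
        if not 0 <= self.floor < 1:
            raise ValueError("floor must be in [0, 1)")
        if not 0 < self.energy_band < 1:
            raise ValueError("energy_band must be in (0, 1)")
        if self.rise_anchor < 0:
            raise ValueError("rise_anchor must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreShape":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class MNIResult:
    """Per-nutrient scores and the 0-100 composite for one person."""

    person_id: str
    per_nutrient: Mapping[str, float]
    mni: float
    mni_10pt: float
    library_version: str
    target_kcal: float
    imputed_nutrients: Tuple[str, ...] = field(default_factory=tuple)


def _piecewise(intake: float, lower: Optional[float], upper: Optional[float], shape: ScoreShape) -> float:
    if intake < 0:
        raise ValueError("intake must be nonnegative")
    if lower is not None and intake < lower:
        span = lower - shape.rise_anchor
        if span <= 0:
            return 0.0
        return min(1.0, max(0.0, (intake - shape.rise_anchor) / span))
    if upper is not None and intake > upper:
        if upper == 0:
            return 0.0
        zero_at = shape.fall_span * upper
        return min(1.0, max(0.0, (zero_at - intake) / (zero_at - upper)))
    return 1.0


def score_nutrient(intake: float, rng: ReferenceRange, shape: ScoreShape = ScoreShape()) -> float:
    """Score one nutrient's intake (in the range's unit) in [0, 1]."""
    return _piecewise(intake, rng.lower, rng.upper, shape)


def score_energy(
    observed_kcal: float,
    target: EnergyTarget | float,
    shape: ScoreShape = ScoreShape(),
) -> float:
    """Score agreement of observed calories with the target band."""
    target_kcal = target.target_kcal if isinstance(target, EnergyTarget) else float(target)
    if target_kcal <= 0:
        raise ValueError("target_kcal must be positive")
    lower = (1.0 - shape.energy_band) * target_kcal
    upper = (1.0 + shape.energy_band) * target_kcal
    return _piecewise(observed_kcal, lower, upper, shape)


def absolute_bounds(
    nutrient: str,
    rng: ReferenceRange,
    weight_kg: float,
    target_kcal: float,
    shape: ScoreShape = ScoreShape(),
) -> Tuple[Optional[float], Optional[float]]:
    """Resolved range converted to the nutrient's intake unit (amount/day).

    %energy bands use the target energy and the Atwater factor; g/kg ranges
    use body weight, with the protein %-energy cap applied to the upper bound.
    """
    lower, upper = rng.lower, rng.upper
    if rng.unit == "%energy":
        factor = target_kcal / 100.0 / KCAL_PER_G[nutrient]
        lower = None if lower is None else lower * factor
        upper = None if upper is None else upper * factor
    elif rng.unit == "g/kg":
        lower = None if lower is None else lower * weight_kg
        upper = None if upper is None else upper * weight_kg
        if nutrient == "protein":
            cap = shape.protein_energy_cap_pct / 100.0 * target_kcal / KCAL_PER_G["protein"]
            upper = cap if upper is None else min(upper, cap)
    return lower, upper


def aggregate_scores(scores, shape: ScoreShape = ScoreShape()) -> float:
    """Composite index: 100 x geometric mean of floored per-nutrient scores."""
    values = np.asarray(
        list(scores.values()) if isinstance(scores, Mapping) else scores, dtype=float
    )
    if values.size == 0:
        raise ValueError("no scores to aggregate")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("per-nutrient scores must lie in [0, 1]")
    floored = np.maximum(values, shape.floor)
    return min(100.0, 100.0 * math.exp(float(np.mean(np.log(floored)))))


def full_score_intake(
    profile: IndividualProfile,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
) -> DailyIntake:
    """A diet scoring 1.0 on every nutrient for this profile.

    Each nutrient sits at the midpoint of its resolved absolute range (the
    bound itself, comfortably inside the full-score region, for one-sided
    ranges) and energy equals the Mifflin-St Jeor target.
    """
    if library is None:
        library = load_reference_library()
    target = target_energy(profile)
    resolved = resolve_reference_ranges(profile, library)
    amounts: Dict[str, float] = {}
    for code, rng in resolved.items():
        lower, upper = absolute_bounds(code, rng, profile.weight_kg, target.target_kcal, shape)
        if lower is not None and upper is not None:
            amounts[code] = (lower + upper) / 2.0
        elif lower is not None:
            amounts[code] = lower * 1.2
        else:
            amounts[code] = upper * 0.5
    amounts["energy"] = target.target_kcal
    return DailyIntake(person_id=profile.person_id, amounts=amounts)


def to_ten_point(mni: float) -> float:
    """Rescale a 0-100 MNI to the 10-point scale used in regression models."""
    if not 0 <= mni <= 100:
        raise ValueError(f"MNI must be in [0, 100], got {mni}")
    return mni / 10.0


def compute_mni(
    intake: DailyIntake,
    profile: IndividualProfile,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
    impute_missing: bool = False,
) -> MNIResult:
    """Full MNI for one person: resolve, convert, score, aggregate.

    ``intake.amounts`` must cover every nutrient in the library (energy in
    kcal included); with ``impute_missing=True`` absent nutrients are scored
    as zero intake and reported in ``imputed_nutrients`` with a warning.
    """
    if library is None:
        library = load_reference_library()
    resolved = resolve_reference_ranges(profile, library)
    target = target_energy(profile)

    imputed = []
    scores: Dict[str, float] = {}
    for code, rng in resolved.items():
        if code in intake.amounts:
            amount = float(intake.amounts[code])
        elif impute_missing:
            amount = 0.0
            imputed.append(code)
        else:
            raise KeyError(f"intake for {intake.person_id!r} is missing nutrient {code!r}")
        lower, upper = absolute_bounds(code, rng, profile.weight_kg, target.target_kcal, shape)
        scores[code] = _piecewise(amount, lower, upper, shape)
    scores["energy"] = score_energy(intake.energy_kcal, target, shape)
    if imputed:
        warnings.warn(
            f"{intake.person_id}: imputed zero intake for {len(imputed)} nutrient(s): "
            + ", ".join(sorted(imputed)),
            stacklevel=2,
        )

    mni = aggregate_scores(scores, shape)
    return MNIResult(
        person_id=intake.person_id,
        per_nutrient=scores,
        mni=mni,
        mni_10pt=to_ten_point(mni),
        library_version=library.version,
        target_kcal=target.target_kcal,
        imputed_nutrients=tuple(imputed),
    )


# -- vectorized cohort scoring ---------------------------------------------


def _piecewise_array(x: np.ndarray, lower: np.ndarray, upper: np.ndarray, shape: ScoreShape) -> np.ndarray:
    """Vectorized piecewise-linear score; NaN bounds mean an open side."""
    s = np.ones_like(x, dtype=float)
    has_l = ~np.isnan(lower)
    has_u = ~np.isnan(upper)

    below = has_l & (x < lower)
    span = lower - shape.rise_anchor
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = (x - shape.rise_anchor) / span
    rise = np.where(span > 0, rise, 0.0)
    s = np.where(below, np.clip(rise, 0.0, 1.0), s)

    above = has_u & (x > upper)
    zero_at = shape.fall_span * upper
    with np.errstate(divide="ignore", invalid="ignore"):
        fall = (zero_at - x) / (zero_at - upper)
    fall = np.where(upper > 0, fall, 0.0)
    s = np.where(above, np.clip(fall, 0.0, 1.0), s)
    return s


def resolve_bounds_frame(
    profiles: pd.DataFrame,
    library: ReferenceLibrary,
    shape: ScoreShape = ScoreShape(),
    target_kcal: Optional[np.ndarray] = None,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-person absolute (lower, upper) bound arrays for every nutrient.

    ``profiles`` needs columns sex, age_y, weight_kg, height_cm, smoker,
    pregnant, lactating, hypertension (and activity_level if ``target_kcal``
    is not supplied). NaN entries mark open sides. Mirrors the scalar
    resolution chain exactly (lactation > pregnancy > general rows, then
    condition modifiers in deterministic order).
    """
    n = len(profiles)
    sex = profiles["sex"].to_numpy()
    age = profiles["age_y"].to_numpy(dtype=float)
    pregnant = profiles["pregnant"].to_numpy(dtype=bool)
    lactating = profiles["lactating"].to_numpy(dtype=bool)
    weight = profiles["weight_kg"].to_numpy(dtype=float)
    if target_kcal is None:
        target_kcal = target_energy_frame(profiles)["target_kcal"].to_numpy()

    rows = library.rows_frame()
    bounds: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for nutrient, grp in rows.groupby("nutrient", sort=False):
        lower = np.full(n, np.nan)
        upper = np.full(n, np.nan)
        matched = np.zeros(n, dtype=bool)
        if grp["unit"].nunique() > 1:
            raise ReferenceDataError(f"mixed units for nutrient {nutrient!r}")
        for tier_preg, tier_lact in ((False, False), (True, False), (False, True)):
            tier = grp[(grp["pregnant"] == tier_preg) & (grp["lactating"] == tier_lact)]
            for row in tier.itertuples():
                mask = (sex == row.sex) & (age >= row.age_min) & (age < row.age_max + 1)
                if tier_preg:
                    mask &= pregnant
                if tier_lact:
                    mask &= lactating
                lower[mask] = row.lower
                upper[mask] = row.upper
                matched |= mask
        if not matched.all():
            bad_age = age[~matched][0]
            raise ReferenceDataError(
                f"no life-stage row for nutrient {nutrient!r} covers age {bad_age:g}"
            )
        bounds[nutrient] = (lower, upper)

    # condition modifiers, same deterministic order as the scalar path
    flags = {
        "smoker": profiles["smoker"].to_numpy(dtype=bool),
        "hypertension": profiles["hypertension"].to_numpy(dtype=bool),
        "pregnancy": pregnant,
        "lactation": lactating,
        "user-defined": np.ones(n, dtype=bool),
    }
    for condition in MODIFIER_ORDER:
        for rule in library.modifiers:
            if rule.condition != condition or rule.nutrient not in bounds:
                continue
            lower, upper = bounds[rule.nutrient]
            arr = lower if rule.bound == "lower" else upper
            mask = flags[condition]
            if rule.action == "set":
                arr[mask] = rule.amount
            elif rule.action == "add":
                arr[mask] = np.where(np.isnan(arr[mask]), 0.0, arr[mask]) + rule.amount
            else:
                arr[mask] = arr[mask] * rule.amount
            both = ~np.isnan(lower) & ~np.isnan(upper)
            if np.any(lower[both] > upper[both]):
                raise ReferenceDataError(
                    f"modifier {rule.condition}/{rule.nutrient} produced lower > upper"
                )

    # convert %energy and g/kg ranges to absolute amounts per day
    unit_by_nutrient = rows.drop_duplicates("nutrient").set_index("nutrient")["unit"]
    for nutrient, (lower, upper) in bounds.items():
        unit = unit_by_nutrient[nutrient]
        if unit == "%energy":
            factor = target_kcal / 100.0 / KCAL_PER_G[nutrient]
            bounds[nutrient] = (lower * factor, upper * factor)
        elif unit == "g/kg":
            lower = lower * weight
            upper = upper * weight
            if nutrient == "protein":
                cap = shape.protein_energy_cap_pct / 100.0 * target_kcal / KCAL_PER_G["protein"]
                upper = np.where(np.isnan(upper), cap, np.minimum(upper, cap))
            bounds[nutrient] = (lower, upper)
    return bounds


def target_energy_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Mifflin-St Jeor targets for a profile table.

    Requires an ``activity_level`` column (use the scalar API or
    ``derive_activity_level`` to map questionnaire items first).
    """
    from .energy import ACTIVITY_MULTIPLIERS, MSJ_AGE, MSJ_CONST, MSJ_HEIGHT, MSJ_WEIGHT

    weight = profiles["weight_kg"].to_numpy(dtype=float)
    height = profiles["height_cm"].to_numpy(dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    const = np.where(profiles["sex"].to_numpy() == "male", MSJ_CONST["male"], MSJ_CONST["female"])
    bmr = (
        MSJ_WEIGHT * weight
        + MSJ_HEIGHT * height
        + MSJ_AGE * profiles["age_y"].to_numpy(dtype=float)
        + const
    )
    levels = profiles["activity_level"].to_numpy(dtype=int)
    if np.any((levels < 1) | (levels > 5)):
        raise ValueError("activity_level must be in 1..5")
    mult = np.array([ACTIVITY_MULTIPLIERS[lv] for lv in range(1, 6)])[levels - 1]
    return pd.DataFrame(
        {"bmr": bmr, "activity_level": levels, "multiplier": mult, "target_kcal": bmr * mult},
        index=profiles.index,
    )


def score_cohort(
    profiles: pd.DataFrame,
    intakes: pd.DataFrame,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
) -> pd.DataFrame:
    """Vectorized MNI for a cohort.

    ``profiles``: one row per person (person_id, sex, age_y, weight_kg,
    height_cm, smoker, pregnant, lactating, hypertension, activity_level).
    ``intakes``: one row per person (person_id + one column per nutrient code,
    energy included). Rows are aligned on person_id.

    Returns a DataFrame with person_id, target_kcal, mni, mni_10pt and one
    ``score_<nutrient>`` column per nutrient. Agrees with the scalar
    ``compute_mni`` to floating-point round-off.
    """
    if library is None:
        library = load_reference_library()
    profiles = profiles.reset_index(drop=True)
    intakes = (
        intakes.set_index("person_id")
        .loc[profiles["person_id"].to_numpy()]
        .reset_index()
    )
    targets = target_energy_frame(profiles)
    target_kcal = targets["target_kcal"].to_numpy()
    bounds = resolve_bounds_frame(profiles, library, shape, target_kcal=target_kcal)

    score_cols: Dict[str, np.ndarray] = {}
    for nutrient, (lower, upper) in bounds.items():
        if nutrient not in intakes.columns:
            raise KeyError(f"intake table is missing nutrient column {nutrient!r}")
        x = intakes[nutrient].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValueError(f"negative intake in column {nutrient!r}")
        score_cols[nutrient] = _piecewise_array(x, lower, upper, shape)

    energy_obs = intakes["energy"].to_numpy(dtype=float)
    e_lower = (1.0 - shape.energy_band) * target_kcal
    e_upper = (1.0 + shape.energy_band) * target_kcal
    score_cols["energy"] = _piecewise_array(energy_obs, e_lower, e_upper, shape)

    matrix = np.column_stack([score_cols[c] for c in score_cols])
    floored = np.maximum(matrix, shape.floor)
    mni = np.minimum(100.0 * np.exp(np.mean(np.log(floored), axis=1)), 100.0)

    out = pd.DataFrame({"person_id": profiles["person_id"], "target_kcal": target_kcal})
    out["mni"] = mni
    out["mni_10pt"] = mni / 10.0
    for name, col in score_cols.items():
        out[f"score_{name}"] = col
    return out


class MNIScorer:
    """Configured scorer: a reference library plus a score shape.

    The object form mirrors how model objects are configured once and applied
    to many datasets; ``score`` handles one person, ``score_cohort`` a table.
    """

    def __init__(
        self,
        library: Optional[ReferenceLibrary] = None,
        shape: ScoreShape = ScoreShape(),
    ) -> None:
        self.library = library if library is not None else load_reference_library()
        self.shape = shape

    def score(self, intake: DailyIntake, profile: IndividualProfile, **kwargs) -> MNIResult:
        return compute_mni(intake, profile, self.library, self.shape, **kwargs)

    def score_cohort(self, profiles: pd.DataFrame, intakes: pd.DataFrame) -> pd.DataFrame:
        return score_cohort(profiles, intakes, self.library, self.shape)

    def plot_distribution(self, scores: pd.DataFrame, ax=None, **hist_kwargs):
        """Histogram of cohort MNI scores (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(scores["mni"], bins=hist_kwargs.pop("bins", 30), **hist_kwargs)
        ax.set_xlabel("MNI score")
        ax.set_ylabel("count")
        return ax
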