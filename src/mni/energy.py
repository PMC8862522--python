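"""Individual energy targets: Mifflin-St Jeor BMR x 5-level activity factor.

The activity level is derived from four yes/no questionnaire items on
vigorous/moderate work and recreational activity: 5 if both vigorous items
are "yes", 4 if exactly one is, 3 if neither vigorous but both moderate
items are "yes", 2 if exactly one moderate item is, and 1 otherwise.
Missing items count as "no" (the catch-all level-1 rule), with a warning
flag carried on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import YES, ActivityResponses, IndividualProfile

__all__ = [
    "ACTIVITY_MULTIPLIERS",
    "EnergyTarget",
    "derive_activity_level",
    "bmr_mifflin_st_jeor",
    "activity_multiplier",
    "target_energy",
    "passes_energy_filter",
]

# Sedentary .. very active multipliers applied to BMR.
ACTIVITY_MULTIPLIERS = {1: 1.20, 2: 1.375, 3: 1.55, 4: 1.725, 5: 1.90}

# Mifflin-St Jeor coefficients (kcal/day): 10*W[kg] + 6.25*H[cm] - 5*A[y] + c_sex
MSJ_WEIGHT = 10.0
MSJ_HEIGHT = 6.25
MSJ_AGE = -5.0
MSJ_CONST = {"male": 5.0, "female": -161.0}

ENERGY_RATIO_LOW = 0.33
ENERGY_RATIO_HIGH = 3.0


@dataclass(frozen=True)
class EnergyTarget:
    """BMR, activity level/multiplier and the resulting target kcal/day."""

    bmr: float
    activity_level: int
    multiplier: float
    target_kcal: float
    had_missing_responses: bool = False

    def __post_init__(self) -> None:
        if self.activity_level not in ACTIVITY_MULTIPLIERS:
            raise ValueError("activity_level must be in 1..5")
        if abs(self.multiplier - ACTIVITY_MULTIPLIERS[self.activity_level]) > 1e-12:
            raise ValueError("multiplier inconsistent with activity level")
        if self.target_kcal <= 0:
            raise ValueError("target_kcal must be positive")


def derive_activity_level(responses: ActivityResponses) -> int:
    """Map the four questionnaire items to the 1-5 activity scale."""
    vig = (responses.vigorous_work == YES) + (responses.vigorous_rec == YES)
    mod = (responses.moderate_work == YES) + (responses.moderate_rec == YES)
    if vig == 2:
        return 5
    if vig == 1:
        return 4
    if mod == 2:
        return 3
    if mod == 1:
        return 2
    return 1


def bmr_mifflin_st_jeor(sex: str, weight_kg: float, height_cm: float, age_y: float) -> float:
    """Basal metabolic rate in kcal/day.

    male: 10W + 6.25H - 5A + 5; female: 10W + 6.25H - 5A - 161.
    """
    if sex not in MSJ_CONST:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return MSJ_WEIGHT * weight_kg + MSJ_HEIGHT * height_cm + MSJ_AGE * age_y + MSJ_CONST[sex]


def activity_multiplier(level: int) -> float:
    try:
        return ACTIVITY_MULTIPLIERS[level]
    except KeyError:
        raise ValueError(f"activity level must be in 1..5, got {level!r}") from None


def target_energy(profile: IndividualProfile) -> EnergyTarget:
    """Target calories = Mifflin-St Jeor BMR x activity multiplier."""
    if profile.activity_level is not None:
        level = profile.activity_level
        missing = False
    elif profile.activity is not None:
        level = derive_activity_level(profile.activity)
        missing = profile.activity.any_missing
    else:
        level = 1
        missing = True
    bmr = bmr_mifflin_st_jeor(profile.sex, profile.weight_kg, profile.height_cm, profile.age_y)
    mult = activity_multiplier(level)
    return EnergyTarget(
        bmr=bmr,
        activity_level=level,
        multiplier=mult,
        target_kcal=bmr * mult,
        had_missing_responses=missing,
    )


def passes_energy_filter(observed_kcal: float, target_kcal: float) -> tuple[bool, float]:
    """Plausibility filter: strict 0.33 < observed/target < 3.0.

    Returns ``(passes, ratio)``.
    """
    if target_kcal <= 0:
        raise ValueError("target_kcal must be positive")
    if observed_kcal < 0:
        raise ValueError("observed energy must be nonnegative")
    ratio = observed_kcal / target_kcal
    return ENERGY_RATIO_LOW < ratio < ENERGY_RATIO_HIGH, ratio
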