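"""Shared domain types: individual profiles, activity responses, daily intakes.

These are plain dataclasses used across the reference, energy and scoring
layers. Amounts are always in the units of the reference snapshot (g, mg, ug,
kcal); anthropometrics are kg and cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

YES = "yes"
NO = "no"
MISSING = "missing"

_VALID_RESPONSES = {YES, NO, MISSING}


@dataclass(frozen=True)
class ActivityResponses:
    """Yes/no answers to the four physical-activity questionnaire items.

    Field names follow the NHANES questionnaire variables they default-map to
    (vigorous work paq605, vigorous recreation paq650, moderate work paq620,
    moderate recreation paq655). Any item may be ``"missing"``.
    """

    vigorous_work: str = MISSING
    vigorous_rec: str = MISSING
    moderate_work: str = MISSING
    moderate_rec: str = MISSING

    def __post_init__(self) -> None:
        for name in ("vigorous_work", "vigorous_rec", "moderate_work", "moderate_rec"):
            value = getattr(self, name)
            if value not in _VALID_RESPONSES:
                raise ValueError(
                    f"activity response {name!r} must be one of {sorted(_VALID_RESPONSES)}, "
                    f"got {value!r}"
                )

    @property
    def any_missing(self) -> bool:
        return MISSING in (
            self.vigorous_work,
            self.vigorous_rec,
            self.moderate_work,
            self.moderate_rec,
        )


@dataclass(frozen=True)
class IndividualProfile:
    """Everything personalization needs for one person.

    ``activity_level`` (1-5), when given, takes precedence over raw
    questionnaire ``activity`` responses.
    """

    person_id: str
    sex: str  # "male" | "female"
    age_y: float
    weight_kg: float
    height_cm: float
    smoker: bool = False
    pregnant: bool = False
    lactating: bool = False
    hypertension: bool = False
    activity: Optional[ActivityResponses] = None
    activity_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.sex == "male" and (self.pregnant or self.lactating):
            raise ValueError("pregnancy/lactation require sex='female'")
        if self.age_y < 0:
            raise ValueError("age must be nonnegative")
        if self.activity_level is not None and self.activity_level not in range(1, 6):
            raise ValueError("activity_level must be an integer in 1..5")


@dataclass(frozen=True)
class DailyIntake:
    """One person-day (or two-day average) of nutrient amounts.

    ``amounts`` maps nutrient codes to amounts per day in the snapshot units
    and must include ``energy`` in kcal.
    """

    person_id: str
    amounts: Mapping[str, float] = field(default_factory=dict)
    day_count: int = 1

    def __post_init__(self) -> None:
        if self.day_count not in (1, 2):
            raise ValueError("day_count must be 1 or 2")
        for code, amount in self.amounts.items():
            if amount < 0:
                raise ValueError(f"negative intake for {code!r}: {amount}")

    @property
    def energy_kcal(self) -> float:
        try:
            return float(self.amounts["energy"])
        except KeyError:
            raise KeyError(f"intake for {self.person_id!r} has no 'energy' entry") from None
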