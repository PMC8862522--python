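"""Dietary Reference Intake (DRI) reference library.

The library is a versioned snapshot of per-nutrient optimal-intake ranges
stratified by life-stage group (sex x age interval x pregnancy x lactation),
shipped as plain CSV tables under ``mni/data/``, plus condition modifiers
(e.g. the smoker vitamin-C increment). ``resolve_reference_ranges`` turns the
library plus an individual's characteristics into one range per nutrient.

Ranges are kept in their native units: most nutrients are absolute amounts
per day, while the AMDR-style macronutrient bands are % of energy and protein
is g per kg body weight. Converting those to absolute g/day needs the
person's weight and energy target and therefore happens in the scoring layer,
so resolution itself never depends on anthropometrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import yaml

from .types import IndividualProfile

__all__ = [
    "NutrientSpec",
    "LifeStageKey",
    "ReferenceRange",
    "ModifierRule",
    "ReferenceLibrary",
    "ReferenceDataError",
    "load_reference_library",
    "resolve_reference_ranges",
]

VALID_UNITS = {"g", "mg", "ug", "kcal", "%energy", "g/kg"}
VALID_BASES = {"RDA", "AI", "AMDR", "UL", "FDA-limit", "energy-target"}
VALID_DIRECTIONS = {"target", "limit", "adequacy"}
VALID_CATEGORIES = {"macronutrient", "vitamin", "mineral", "other"}

#: deterministic order in which condition modifiers are applied
MODIFIER_ORDER = ("smoker", "hypertension", "pregnancy", "lactation", "user-defined")


class ReferenceDataError(ValueError):
    """Raised when the reference snapshot is malformed or cannot cover a profile."""


@dataclass(frozen=True)
class NutrientSpec:
    code: str
    display_name: str
    unit: str
    category: str
    direction: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ReferenceDataError(f"{self.code}: unknown unit {self.unit!r}")
        if self.category not in VALID_CATEGORIES:
            raise ReferenceDataError(f"{self.code}: unknown category {self.category!r}")
        if self.direction not in VALID_DIRECTIONS:
            raise ReferenceDataError(f"{self.code}: unknown direction {self.direction!r}")


@dataclass(frozen=True)
class LifeStageKey:
    """One life-stage stratum: sex, closed age interval, pregnancy, lactation."""

    sex: str
    age_min_y: float
    age_max_y: float
    pregnancy: bool = False
    lactation: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ReferenceDataError(f"life-stage sex must be male/female, got {self.sex!r}")
        if self.age_min_y > self.age_max_y:
            raise ReferenceDataError("life-stage age_min must be <= age_max")
        if (self.pregnancy or self.lactation) and self.sex != "female":
            raise ReferenceDataError("pregnancy/lactation life stages must be female")

    def covers(self, sex: str, age_y: float) -> bool:
        # DRI age groups are integer brackets: a 18.5-year-old belongs to the
        # 14-18 group until turning 19, so the interval covers [min, max + 1).
        return sex == self.sex and self.age_min_y <= age_y < self.age_max_y + 1


@dataclass(frozen=True)
class ReferenceRange:
    """Optimal intake interval [lower, upper] for one nutrient (either side open)."""

    nutrient: str
    lower: Optional[float]
    upper: Optional[float]
    basis: str
    unit: str

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ReferenceDataError(f"{self.nutrient}: range needs lower and/or upper")
        for bound in (self.lower, self.upper):
            if bound is not None and (not math.isfinite(bound) or bound < 0):
                raise ReferenceDataError(f"{self.nutrient}: bounds must be finite and >= 0")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ReferenceDataError(
                f"{self.nutrient}: lower {self.lower} exceeds upper {self.upper}"
            )
        if self.basis not in VALID_BASES:
            raise ReferenceDataError(f"{self.nutrient}: unknown basis {self.basis!r}")
        if self.unit not in VALID_UNITS:
            raise ReferenceDataError(f"{self.nutrient}: unknown unit {self.unit!r}")


@dataclass(frozen=True)
class ModifierRule:
    """Adjustment of one bound of one nutrient's range for a condition."""

    condition: str
    nutrient: str
    bound: str  # "lower" | "upper"
    action: str  # "set" | "add" | "multiply"
    amount: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.condition not in MODIFIER_ORDER:
            raise ReferenceDataError(f"unknown modifier condition {self.condition!r}")
        if self.bound not in ("lower", "upper"):
            raise ReferenceDataError("modifier bound must be 'lower' or 'upper'")
        if self.action not in ("set", "add", "multiply"):
            raise ReferenceDataError("modifier action must be set/add/multiply")

    def apply(self, rng: ReferenceRange) -> ReferenceRange:
        value = getattr(rng, self.bound)
        if self.action == "set":
            new = self.amount
        elif self.action == "add":
            new = (value if value is not None else 0.0) + self.amount
        else:
            if value is None:
                raise ReferenceDataError(
                    f"cannot multiply absent {self.bound} bound of {rng.nutrient}"
                )
            new = value * self.amount
        return replace(rng, **{self.bound: new})  # re-validates invariants


_RangeRow = Tuple[LifeStageKey, ReferenceRange]


class ReferenceLibrary:
    """Immutable collection of nutrient specs, life-stage ranges and modifiers."""

    def __init__(
        self,
        version: str,
        nutrients: Iterable[NutrientSpec],
        rows: Iterable[_RangeRow],
        modifiers: Iterable[ModifierRule] = (),
    ) -> None:
        self.version = version
        self.nutrients: Dict[str, NutrientSpec] = {}
        for spec in nutrients:
            if spec.code in self.nutrients:
                raise ReferenceDataError(f"duplicate nutrient code {spec.code!r}")
            self.nutrients[spec.code] = spec
        self._rows: Dict[str, List[_RangeRow]] = {}
        for key, rng in rows:
            if rng.nutrient not in self.nutrients:
                raise ReferenceDataError(f"range for unknown nutrient {rng.nutrient!r}")
            self._rows.setdefault(rng.nutrient, []).append((key, rng))
        self.modifiers: Tuple[ModifierRule, ...] = tuple(modifiers)
        for rule in self.modifiers:
            if rule.nutrient not in self.nutrients:
                raise ReferenceDataError(f"modifier for unknown nutrient {rule.nutrient!r}")
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        for code, spec in self.nutrients.items():
            if spec.direction == "target" and code == "energy":
                continue  # the energy band comes from the energy module
            rows = self._rows.get(code, [])
            if not rows:
                raise ReferenceDataError(f"nutrient {code!r} has no reference ranges")
            self._check_no_overlap(code, rows)
            for sex in ("male", "female"):
                self._check_adult_coverage(code, rows, sex)

    @staticmethod
    def _check_no_overlap(code: str, rows: List[_RangeRow]) -> None:
        by_stratum: Dict[Tuple[str, bool, bool], List[LifeStageKey]] = {}
        for key, _ in rows:
            by_stratum.setdefault((key.sex, key.pregnancy, key.lactation), []).append(key)
        for keys in by_stratum.values():
            keys = sorted(keys, key=lambda k: k.age_min_y)
            for a, b in zip(keys, keys[1:]):
                if b.age_min_y <= a.age_max_y:
                    raise ReferenceDataError(
                        f"overlapping life-stage rows for {code!r}: "
                        f"[{a.age_min_y},{a.age_max_y}] and [{b.age_min_y},{b.age_max_y}]"
                    )

    @staticmethod
    def _check_adult_coverage(code: str, rows: List[_RangeRow], sex: str) -> None:
        keys = sorted(
            (k for k, _ in rows if k.sex == sex and not k.pregnancy and not k.lactation),
            key=lambda k: k.age_min_y,
        )
        age = 18.0
        for key in keys:
            if key.age_min_y > age:
                break
            age = max(age, key.age_max_y + 1)
        if age <= 64.0:
            raise ReferenceDataError(
                f"nutrient {code!r} does not cover {sex} adults 18-64 "
                f"(coverage stops at age {age:g})"
            )

    # -- lookups ----------------------------------------------------------

    def range_rows(self, nutrient: str) -> List[_RangeRow]:
        return list(self._rows.get(nutrient, []))

    def lookup(
        self,
        nutrient: str,
        sex: str,
        age_y: float,
        pregnant: bool = False,
        lactating: bool = False,
    ) -> ReferenceRange:
        """Life-stage lookup with a deterministic fallback chain.

        Lactation rows take precedence over pregnancy rows, which take
        precedence over general rows; a pregnant/lactating woman whose
        nutrient has no dedicated row falls back to the general female row,
        mirroring how the DRI tables themselves are organized.
        """
        rows = self._rows.get(nutrient)
        if not rows:
            raise ReferenceDataError(f"no ranges for nutrient {nutrient!r}")
        tiers: List[Tuple[bool, bool]] = []
        if lactating:
            tiers.append((False, True))
        if pregnant:
            tiers.append((True, False))
        tiers.append((False, False))
        for preg, lact in tiers:
            for key, rng in rows:
                if key.pregnancy == preg and key.lactation == lact and key.covers(sex, age_y):
                    return rng
        raise ReferenceDataError(
            f"no life-stage row for nutrient {nutrient!r} covers {sex} age {age_y:g}"
        )

    def rows_frame(self) -> pd.DataFrame:
        """All range rows as a tidy DataFrame (for vectorized cohort scoring)."""
        records = []
        for code, rows in self._rows.items():
            for key, rng in rows:
                records.append(
                    {
                        "nutrient": code,
                        "sex": key.sex,
                        "age_min": key.age_min_y,
                        "age_max": key.age_max_y,
                        "pregnant": key.pregnancy,
                        "lactating": key.lactation,
                        "lower": rng.lower,
                        "upper": rng.upper,
                        "basis": rng.basis,
                        "unit": rng.unit,
                    }
                )
        return pd.DataFrame.from_records(records)


# -- loading ---------------------------------------------------------------


def _normalize_unit(unit: str) -> str:
    return {"µg": "ug", "mcg": "ug"}.get(unit, unit)


def _data_dir() -> Path:
    return Path(str(resources.files("mni").joinpath("data")))


def _parse_bound(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_reference_library(
    path: Optional[str | Path] = None,
    pediatric_zinc_group: str = "9-13",
) -> ReferenceLibrary:
    """Load the packaged DRI snapshot (default) or a snapshot directory.

    A snapshot directory holds ``nutrients.csv``, ``ranges.csv``,
    ``modifiers.csv`` and ``meta.yaml`` (see the packaged copy for the
    schemas). ``pediatric_zinc_group`` may be ``"9-13"`` (published DRI
    grouping, default) or ``"9-14"`` to widen the pediatric zinc row to
    ages 9-14 (shifting the adolescent rows to start at 15).
    """
    if pediatric_zinc_group not in ("9-13", "9-14"):
        raise ValueError("pediatric_zinc_group must be '9-13' or '9-14'")
    base = Path(path) if path is not None else _data_dir()
    if not base.is_dir():
        raise ReferenceDataError(f"reference snapshot directory not found: {base}")

    meta = yaml.safe_load((base / "meta.yaml").read_text()) if (base / "meta.yaml").exists() else {}
    version = str(meta.get("version", base.name))

    nutrients_df = pd.read_csv(base / "nutrients.csv", dtype=str)
    specs = [
        NutrientSpec(
            code=row.code,
            display_name=row.display_name,
            unit=_normalize_unit(row.unit),
            category=row.category,
            direction=row.direction,
        )
        for row in nutrients_df.itertuples()
    ]

    ranges_df = pd.read_csv(base / "ranges.csv")
    rows: List[_RangeRow] = []
    for row in ranges_df.itertuples():
        age_min, age_max = float(row.age_min), float(row.age_max)
        if row.nutrient == "zinc" and pediatric_zinc_group == "9-14":
            if (age_min, age_max) == (9.0, 13.0):
                age_max = 14.0
            elif (age_min, age_max) == (14.0, 18.0):
                age_min = 15.0
        sexes = ("male", "female") if row.sex == "any" else (str(row.sex),)
        rng = ReferenceRange(
            nutrient=str(row.nutrient),
            lower=_parse_bound(row.lower),
            upper=_parse_bound(row.upper),
            basis=str(row.basis),
            unit=_normalize_unit(str(row.unit)),
        )
        for sex in sexes:
            if sex == "male" and (bool(row.pregnant) or bool(row.lactating)):
                continue
            key = LifeStageKey(
                sex=sex,
                age_min_y=age_min,
                age_max_y=age_max,
                pregnancy=bool(row.pregnant),
                lactation=bool(row.lactating),
            )
            rows.append((key, rng))

    modifiers_path = base / "modifiers.csv"
    modifiers: List[ModifierRule] = []
    if modifiers_path.exists():
        for row in pd.read_csv(modifiers_path).itertuples():
            modifiers.append(
                ModifierRule(
                    condition=str(row.condition),
                    nutrient=str(row.nutrient),
                    bound=str(row.bound),
                    action=str(row.action),
                    amount=float(row.amount),
                    unit=_normalize_unit(str(row.unit)),
                )
            )

    return ReferenceLibrary(version=version, nutrients=specs, rows=rows, modifiers=modifiers)


# -- resolution ------------------------------------------------------------


def active_conditions(profile: IndividualProfile) -> Tuple[str, ...]:
    flags = {
        "smoker": profile.smoker,
        "hypertension": profile.hypertension,
        "pregnancy": profile.pregnant,
        "lactation": profile.lactating,
        "user-defined": True,
    }
    return tuple(c for c in MODIFIER_ORDER if flags[c])


def resolve_reference_ranges(
    profile: IndividualProfile,
    library: ReferenceLibrary,
    extra_modifiers: Iterable[ModifierRule] = (),
) -> Dict[str, ReferenceRange]:
    """One reference range per non-energy nutrient for this individual.

    Pure in (profile, library): life-stage lookup first, then condition
    modifiers in the fixed order smoker -> hypertension -> pregnancy ->
    lactation -> user-defined. The energy band is produced by the energy
    module, not here.
    """
    resolved: Dict[str, ReferenceRange] = {}
    for code in library.nutrients:
        if code == "energy":
            continue
        resolved[code] = library.lookup(
            code, profile.sex, profile.age_y, profile.pregnant, profile.lactating
        )
    conditions = active_conditions(profile)
    all_rules = list(library.modifiers) + list(extra_modifiers)
    for condition in conditions:
        for rule in all_rules:
            if rule.condition == condition and rule.nutrient in resolved:
                resolved[rule.nutrient] = rule.apply(resolved[rule.nutrient])
    return resolved
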