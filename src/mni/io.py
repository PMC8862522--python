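"""Readers and writers for the documented table schemas.

All delimited files are UTF-8 CSV with a header row; the canonical missing
sentinel is an empty field. NHANES SAS XPORT (XPT) files are read through
``pandas.read_sas`` and renamed onto the canonical schema via a
``ColumnMapping``; XPT support is read-only. Readers validate and fail with
a diagnostic naming the file/row/column — malformed input is never silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ActivityResponses, DailyIntake, IndividualProfile, MISSING

__all__ = [
    "ColumnMapping",
    "NHANES_INTAKE_ALIASES",
    "NHANES_PROFILE_ALIASES",
    "LB_TO_KG",
    "IN_TO_CM",
    "read_intake_table",
    "write_intake_table",
    "read_profile_table",
    "write_profile_table",
    "read_xpt",
    "profiles_from_frame",
    "intakes_from_frame",
]

LB_TO_KG = 0.45359237
IN_TO_CM = 2.54

#: default NHANES total-nutrient-file aliases (day-1 variable names; the
#: day-2 file uses dr2t*). This is configuration data, editable per study.
NHANES_INTAKE_ALIASES: Dict[str, str] = {
    "seqn": "person_id",
    "dr1tkcal": "energy",
    "dr1tprot": "protein",
    "dr1tcarb": "carbohydrate",
    "dr1ttfat": "total_fat",
    "dr1tsfat": "saturated_fat",
    "dr1tmfat": "monounsaturated_fat",
    "dr1tpfat": "polyunsaturated_fat",
    "dr1tfibe": "fiber",
    "dr1tchol": "cholesterol",
    "dr1tvara": "vitamin_a",
    "dr1tvb1": "thiamin",
    "dr1tvb2": "riboflavin",
    "dr1tniac": "niacin",
    "dr1tvb5": "pantothenic_acid",
    "dr1tvb6": "vitamin_b6",
    "dr1tfdfe": "folate",
    "dr1tvb12": "vitamin_b12",
    "dr1tvc": "vitamin_c",
    "dr1tvd": "vitamin_d",
    "dr1tatoc": "vitamin_e",
    "dr1tvk": "vitamin_k",
    "dr1tcalc": "calcium",
    "dr1tiron": "iron",
    "dr1tmagn": "magnesium",
    "dr1tphos": "phosphorus",
    "dr1tsodi": "sodium",
    "dr1tpota": "potassium",
    "dr1tsele": "selenium",
    "dr1tzinc": "zinc",
    "dr1talco": "alcohol",
    "dr1tsugr": "sugar",
    "dr1tcaff": "caffeine",
}

NHANES_PROFILE_ALIASES: Dict[str, str] = {
    "seqn": "person_id",
    "riagendr": "sex",
    "ridageyr": "age_y",
    "bmxwt": "weight_kg",
    "bmxht": "height_cm",
    "smq020": "smoker",
    "ridexprg": "pregnant",
    "bpq020": "hypertension",
    "paq605": "vigorous_work",
    "paq650": "vigorous_rec",
    "paq620": "moderate_work",
    "paq655": "moderate_rec",
    "wtdr2d": "survey_weight",
}


@dataclass(frozen=True)
class ColumnMapping:
    """Source-column -> canonical-field renames plus unit conversions.

    ``rename`` maps source names (case-insensitive) to canonical fields;
    ``scale`` multiplies a canonical column after renaming (e.g. weight in lb
    -> kg with factor ``LB_TO_KG``); ``missing_values`` are sentinel codes
    replaced by NaN.
    """

    rename: Dict[str, str] = field(default_factory=dict)
    scale: Dict[str, float] = field(default_factory=dict)
    missing_values: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        targets = list(self.rename.values())
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            raise ValueError(f"canonical fields mapped more than once: {sorted(dupes)}")
        for factor in self.scale.values():
            if factor == 0:
                raise ValueError("scale factors must be invertible (nonzero)")

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        lower = {c: str(c).lower() for c in df.columns}
        df = df.rename(columns=lower)
        df = df.rename(columns={k.lower(): v for k, v in self.rename.items()})
        for col, factor in self.scale.items():
            if col in df.columns:
                df[col] = df[col].astype(float) * factor
        if self.missing_values:
            df = df.replace(list(self.missing_values), np.nan)
        return df


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # re-raise with the file named
        raise ValueError(f"{path}: could not parse CSV ({exc})") from exc


def read_intake_table(
    path: str | Path,
    mapping: Optional[ColumnMapping] = None,
    nutrient_codes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read a per-person-day nutrient intake table.

    Canonical schema: ``person_id`` (+ optional ``day``) plus one column per
    nutrient code, amounts/day in snapshot units. Unknown columns are kept
    but warned about when ``nutrient_codes`` is given; negative amounts and
    duplicate (person, day) rows are hard errors naming the offending rows.
    """
    df = _read_csv(path)
    if mapping is not None:
        df = mapping.apply(df)
    if "person_id" not in df.columns:
        raise ValueError(f"{path}: intake table needs a person_id column")
    df["person_id"] = df["person_id"].astype(str)

    key_cols = ["person_id"] + (["day"] if "day" in df.columns else [])
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based + header
        raise ValueError(f"{path}: duplicate (person, day) entries at file rows {rows}")

    value_cols = [c for c in df.columns if c not in ("person_id", "day")]
    if nutrient_codes is not None:
        unknown = [c for c in value_cols if c not in nutrient_codes]
        if unknown:
            warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
            df = df.drop(columns=unknown)
            value_cols = [c for c in value_cols if c not in unknown]
    for col in value_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals < 0
        if bad.any():
            rows = (df.index[bad] + 2).tolist()
            raise ValueError(f"{path}: negative amounts in column {col!r} at file rows {rows}")
        df[col] = vals
    return df


def write_intake_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _to_bool(series: pd.Series, column: str, path) -> pd.Series:
    def convert(v):
        if pd.isna(v):
            return False
        s = str(v).strip().lower()
        if s in (_TRUTHY | {"1.0"}):
            return True
        if s in (_FALSY | {"0.0", "nan"}):
            return False
        raise ValueError(f"{path}: column {column!r} has non-boolean value {v!r}")

    return series.map(convert)


PROFILE_REQUIRED = ("person_id", "sex", "age_y", "weight_kg", "height_cm")
PROFILE_FLAGS = ("smoker", "pregnant", "lactating", "hypertension")


def read_profile_table(path: str | Path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """Read a person-profile table into the canonical schema.

    Required: person_id, sex (male/female), age_y, weight_kg, height_cm.
    Optional: the condition flags, activity_level or the four activity
    responses, survey_weight and any pipeline columns.
    """
    df = _read_csv(path)
    if mapping is not None:
        df = mapping.apply(df)
    for col in PROFILE_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: profile table is missing required column {col!r}")
        if df[col].isna().any():
            rows = (df.index[df[col].isna()] + 2).tolist()
            raise ValueError(f"{path}: missing {col!r} at file rows {rows}")
    df["person_id"] = df["person_id"].astype(str)
    sex = df["sex"].astype(str).str.strip().str.lower()
    bad = ~sex.isin(["male", "female"])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: sex must be male/female at file rows {rows}")
    df["sex"] = sex
    for col in ("age_y", "weight_kg", "height_cm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in PROFILE_FLAGS:
        df[col] = _to_bool(df[col], col, path) if col in df.columns else False
    if "activity_level" not in df.columns:
        df["activity_level"] = 1
    df["activity_level"] = df["activity_level"].fillna(1).astype(int)
    return df


def write_profile_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_xpt(path: str | Path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """Read a SAS XPORT (XPT) file; column names are lowercased.

    With a ``ColumnMapping`` (e.g. built from ``NHANES_INTAKE_ALIASES``)
    the result lands on the canonical schema.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_sas(path, format="xport")
    df.columns = [str(c).lower() for c in df.columns]
    if mapping is not None:
        df = mapping.apply(df)
    return df


def profiles_from_frame(df: pd.DataFrame) -> List[IndividualProfile]:
    """Canonical profile rows -> IndividualProfile objects."""
    out = []
    for row in df.itertuples():
        activity = None
        if hasattr(row, "vigorous_work"):
            activity = ActivityResponses(
                vigorous_work=getattr(row, "vigorous_work", MISSING) or MISSING,
                vigorous_rec=getattr(row, "vigorous_rec", MISSING) or MISSING,
                moderate_work=getattr(row, "moderate_work", MISSING) or MISSING,
                moderate_rec=getattr(row, "moderate_rec", MISSING) or MISSING,
            )
        out.append(
            IndividualProfile(
                person_id=str(row.person_id),
                sex=row.sex,
                age_y=float(row.age_y),
                weight_kg=float(row.weight_kg),
                height_cm=float(row.height_cm),
                smoker=bool(getattr(row, "smoker", False)),
                pregnant=bool(getattr(row, "pregnant", False)),
                lactating=bool(getattr(row, "lactating", False)),
                hypertension=bool(getattr(row, "hypertension", False)),
                activity=activity,
                activity_level=int(row.activity_level)
                if hasattr(row, "activity_level")
                else None,
            )
        )
    return out


def intakes_from_frame(df: pd.DataFrame) -> List[DailyIntake]:
    """Canonical intake rows -> DailyIntake objects."""
    nutrient_cols = [c for c in df.columns if c not in ("person_id", "day")]
    return [
        DailyIntake(
            person_id=str(row["person_id"]),
            amounts={c: float(row[c]) for c in nutrient_cols if pd.notna(row[c])},
        )
        for _, row in df.iterrows()
    ]
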