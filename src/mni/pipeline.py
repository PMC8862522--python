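"""NHANES-style validation pipeline for MNI.

Reproduces the study flow: average the two 24-h recalls, apply eligibility
filters (age window, reliable and typical recalls, no special diet, energy
plausibility) plus per-outcome exclusions (psychotropic medication for
depression, cardiovascular medication for CVD, pregnancy for obesity),
dichotomize the four health outcomes, and fit survey-weighted logistic
regressions of each outcome on the 10-point MNI adjusted for age, sex,
race/ethnicity, education and healthcare use.

The regression is a pseudo-maximum-likelihood fit (log-likelihood weighted
by the dietary survey weights) with a probability-weight sandwich variance;
when stratum/PSU design columns are supplied the variance is Taylor
linearized over PSU totals within strata instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .energy import passes_energy_filter, target_energy
from .reference import ReferenceLibrary
from .scoring import ScoreShape, score_cohort
from .types import DailyIntake, IndividualProfile

__all__ = [
    "EligibilityConfig",
    "EligibilityResult",
    "CohortRecord",
    "OutcomeModelResult",
    "SurveyLogit",
    "SurveyLogitResults",
    "OUTCOMES",
    "DEFAULT_COVARIATES",
    "average_recalls",
    "average_recall_frames",
    "apply_eligibility",
    "eligibility_frame",
    "dichotomize_health_rating",
    "dichotomize_depression",
    "dichotomize_obesity",
    "dichotomize_cvd",
    "compute_bmi",
    "standardize_scores",
    "prepare_cohort",
    "fit_outcome_model",
    "run_validation_pipeline",
    "exclusion_audit",
]

OUTCOMES = ("obesity", "health", "depression", "cvd")

DEFAULT_COVARIATES = ("age_y", "sex", "race", "education", "healthcare_use")

CVD_QUESTIONS = ("cvd_chf", "cvd_chd", "cvd_angina", "cvd_heart_attack", "cvd_stroke")

HEALTH_RATINGS = ("excellent", "very good", "good", "fair", "poor")


@dataclass(frozen=True)
class EligibilityConfig:
    """Study-window and filter settings (defaults mirror the validation study)."""

    age_min: float = 18.0
    age_max: float = 64.0
    energy_ratio_low: float = 0.33
    energy_ratio_high: float = 3.0
    #: apply the energy filter to the two-day average (False: each day)
    filter_on_average: bool = True
    #: favorable self-rated health categories; the descriptive-table variant
    #: groups only excellent/very good as favorable
    favorable_health: Tuple[str, ...] = ("excellent", "very good", "good")


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    reasons: Tuple[str, ...]


@dataclass(frozen=True)
class CohortRecord:
    """Profile + averaged intake + outcome fields for one participant."""

    person_id: str
    profile: IndividualProfile
    intake_avg: DailyIntake
    survey_weight: float = 1.0
    recall_reliable: Tuple[bool, bool] = (True, True)
    recall_typical: Tuple[bool, bool] = (True, True)
    special_diet: bool = False
    meds_psychotropic: bool = False
    meds_cardiovascular: bool = False
    phq9_total: Optional[int] = None
    bmi: Optional[float] = None
    cvd_any: Optional[bool] = None
    health_rating: Optional[str] = None
    race: Optional[str] = None
    education: Optional[str] = None
    healthcare_use: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.survey_weight < 0:
            raise ValueError("survey weight must be nonnegative")
        if self.phq9_total is not None and not 0 <= self.phq9_total <= 27:
            raise ValueError("PHQ-9 total must be in [0, 27]")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError("BMI must be positive when present")


# -- recall handling -------------------------------------------------------


def average_recalls(day1: DailyIntake, day2: DailyIntake) -> DailyIntake:
    """Arithmetic per-nutrient mean of the two recall days."""
    if day1.person_id != day2.person_id:
        raise ValueError("recall days belong to different persons")
    if set(day1.amounts) != set(day2.amounts):
        missing = set(day1.amounts) ^ set(day2.amounts)
        raise ValueError(f"recall days cover different nutrients: {sorted(missing)}")
    amounts = {k: (day1.amounts[k] + day2.amounts[k]) / 2.0 for k in day1.amounts}
    return DailyIntake(person_id=day1.person_id, amounts=amounts, day_count=2)


def average_recall_frames(day1: pd.DataFrame, day2: pd.DataFrame) -> pd.DataFrame:
    """Vectorized two-day average; tables aligned on person_id."""
    if set(day1.columns) != set(day2.columns):
        raise ValueError("recall tables have different columns")
    d1 = day1.set_index("person_id").sort_index()
    d2 = day2.set_index("person_id").sort_index()
    if not d1.index.equals(d2.index):
        raise ValueError("recall tables cover different persons")
    return ((d1 + d2) / 2.0).reset_index()


# -- dichotomizers ---------------------------------------------------------


def dichotomize_health_rating(
    rating: str, favorable: Sequence[str] = ("excellent", "very good", "good")
) -> int:
    """1 for favorable self-rated health, 0 for fair/poor."""
    rating = rating.strip().lower()
    if rating not in HEALTH_RATINGS:
        raise ValueError(f"unknown health rating {rating!r}")
    return int(rating in favorable)


def dichotomize_depression(phq9_total: int) -> int:
    """Depressed mood: PHQ-9 total >= 10."""
    if not 0 <= phq9_total <= 27:
        raise ValueError(f"PHQ-9 total must be in [0, 27], got {phq9_total}")
    return int(phq9_total >= 10)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """BMI = kg / m^2, rounded half-up to one decimal place."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    return math.floor(bmi * 10 + 0.5) / 10.0


def dichotomize_obesity(bmi: float) -> int:
    """Obese: BMI >= 30."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    return int(bmi >= 30)


def dichotomize_cvd(answers: Mapping[str, Optional[bool]] | Sequence[Optional[bool]]) -> Optional[int]:
    """1 if any of the five condition questions is yes; None if all missing."""
    values = list(answers.values()) if isinstance(answers, Mapping) else list(answers)
    if len(values) != 5:
        raise ValueError("expected 5 condition answers")
    known = [v for v in values if v is not None]
    if not known:
        return None
    return int(any(known))


# -- eligibility -----------------------------------------------------------


def apply_eligibility(
    record: CohortRecord,
    analysis: str = "base",
    config: EligibilityConfig = EligibilityConfig(),
) -> EligibilityResult:
    """All failed exclusion codes for one record under one analysis."""
    if analysis not in ("base",) + OUTCOMES:
        raise ValueError(f"unknown analysis {analysis!r}")
    reasons: List[str] = []
    profile = record.profile
    if not config.age_min <= profile.age_y <= config.age_max:
        reasons.append("age_range")
    if not all(record.recall_reliable):
        reasons.append("unreliable_recall")
    if not all(record.recall_typical):
        reasons.append("atypical_diet")
    if record.special_diet:
        reasons.append("special_diet")
    target = target_energy(profile)
    ok, _ = passes_energy_filter(record.intake_avg.energy_kcal, target.target_kcal)
    if not ok:
        reasons.append("energy_ratio")
    if analysis == "depression":
        if record.meds_psychotropic:
            reasons.append("meds_psy")
        if record.phq9_total is None:
            reasons.append("missing_data")
    elif analysis == "cvd":
        if record.meds_cardiovascular:
            reasons.append("meds_cvd")
        if record.cvd_any is None:
            reasons.append("missing_data")
    elif analysis == "obesity":
        if profile.pregnant:
            reasons.append("pregnancy")
        if record.bmi is None:
            reasons.append("missing_data")
    elif analysis == "health":
        if record.health_rating is None:
            reasons.append("missing_data")
    return EligibilityResult(included=not reasons, reasons=tuple(reasons))


def eligibility_frame(
    cohort: pd.DataFrame,
    analysis: str = "base",
    config: EligibilityConfig = EligibilityConfig(),
    energy_ratio: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Vectorized eligibility: one boolean column per exclusion code + ``included``.

    ``cohort`` uses the flat schema (see :func:`prepare_cohort`); an
    ``energy_ratio`` column or array must be available.
    """
    if analysis not in ("base",) + OUTCOMES:
        raise ValueError(f"unknown analysis {analysis!r}")
    if energy_ratio is None:
        energy_ratio = cohort["energy_ratio"].to_numpy(dtype=float)
    age = cohort["age_y"].to_numpy(dtype=float)
    out = pd.DataFrame(index=cohort.index)
    out["age_range"] = (age < config.age_min) | (age > config.age_max)
    out["unreliable_recall"] = ~(
        cohort["recall1_reliable"].astype(bool) & cohort["recall2_reliable"].astype(bool)
    )
    out["atypical_diet"] = ~(
        cohort["recall1_typical"].astype(bool) & cohort["recall2_typical"].astype(bool)
    )
    out["special_diet"] = cohort["special_diet"].astype(bool)
    out["energy_ratio"] = ~(
        (energy_ratio > config.energy_ratio_low) & (energy_ratio < config.energy_ratio_high)
    )
    if analysis == "depression":
        out["meds_psy"] = cohort["meds_psychotropic"].astype(bool)
        out["missing_data"] = cohort["phq9_total"].isna().to_numpy()
    elif analysis == "cvd":
        out["meds_cvd"] = cohort["meds_cardiovascular"].astype(bool)
        out["missing_data"] = cohort[list(CVD_QUESTIONS)].isna().all(axis=1).to_numpy()
    elif analysis == "obesity":
        out["pregnancy"] = cohort["pregnant"].astype(bool)
        out["missing_data"] = cohort["bmi"].isna().to_numpy()
    elif analysis == "health":
        out["missing_data"] = cohort["health_rating"].isna().to_numpy()
    out["included"] = ~out.any(axis=1)
    return out


def exclusion_audit(
    cohort: pd.DataFrame,
    analysis: str = "base",
    config: EligibilityConfig = EligibilityConfig(),
    waterfall: bool = False,
) -> pd.DataFrame:
    """Exclusion counts per reason.

    Default: overlapping counts (a record can fail several filters).
    ``waterfall=True`` attributes each excluded record to its first failed
    filter in the fixed column order, so reason counts plus the included
    count sum exactly to the input count.
    """
    flags = eligibility_frame(cohort, analysis, config)
    reasons = [c for c in flags.columns if c != "included"]
    if waterfall:
        remaining = np.ones(len(flags), dtype=bool)
        counts = {}
        for reason in reasons:
            hit = remaining & flags[reason].to_numpy()
            counts[reason] = int(hit.sum())
            remaining &= ~hit
        counts["included"] = int(remaining.sum())
    else:
        counts = {reason: int(flags[reason].sum()) for reason in reasons}
        counts["included"] = int(flags["included"].sum())
    return pd.DataFrame({"count": counts})


# -- scores ----------------------------------------------------------------


def standardize_scores(
    values: np.ndarray | pd.Series, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Center and scale to mean 0 / SD 1 (optionally survey-weighted)."""
    x = np.asarray(values, dtype=float)
    if weights is None:
        mean, sd = float(np.mean(x)), float(np.std(x))
    else:
        w = np.asarray(weights, dtype=float)
        mean = float(np.average(x, weights=w))
        sd = float(math.sqrt(np.average((x - mean) ** 2, weights=w)))
    if sd == 0:
        raise ValueError("cannot standardize a constant score vector")
    return (x - mean) / sd


# -- survey-weighted logistic regression -----------------------------------


class SurveyLogitResults:
    """Estimates, robust variances and derived odds ratios."""

    def __init__(
        self,
        params: np.ndarray,
        cov: np.ndarray,
        exog_names: Sequence[str],
        n_unweighted: int,
        n_weighted: float,
        vcov_kind: str,
    ) -> None:
        self.params = pd.Series(params, index=list(exog_names))
        self.cov_params = pd.DataFrame(cov, index=list(exog_names), columns=list(exog_names))
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=list(exog_names))
        self.n_unweighted = n_unweighted
        self.n_weighted = n_weighted
        self.vcov_kind = vcov_kind

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * scipy.stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_lower": np.exp(ci["lower"]),
                "ci_upper": np.exp(ci["upper"]),
                "p_value": self.pvalues,
            }
        )

    def summary(self) -> str:
        table = pd.DataFrame(
            {
                "coef": self.params,
                "robust se": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
                "OR": np.exp(self.params),
            }
        )
        header = (
            f"Survey-weighted logistic regression ({self.vcov_kind} variance)\n"
            f"n = {self.n_unweighted} (weighted N = {self.n_weighted:.1f})\n"
        )
        return header + table.to_string(float_format=lambda v: f"{v:.4f}")


class SurveyLogit:
    """Weighted logistic regression with design-based robust variance.

    Point estimates maximize the weight-multiplied log-likelihood (fit via
    statsmodels GLM with frequency weights); the reported variance is the
    probability-weight sandwich, or the stratified/clustered Taylor
    linearization when ``strata``/``psu`` are given.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        weights: Optional[np.ndarray] = None,
        exog_names: Optional[Sequence[str]] = None,
        strata: Optional[np.ndarray] = None,
        psu: Optional[np.ndarray] = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        n = len(self.endog)
        self.weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        self.strata = None if strata is None else np.asarray(strata)
        self.psu = None if psu is None else np.asarray(psu)
        uniq = np.unique(self.endog)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("outcome must be binary 0/1")
        if len(uniq) < 2:
            raise ValueError("outcome has no variation; model is not estimable")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        predictors: Sequence[str],
        weight_col: Optional[str] = None,
        strata_col: Optional[str] = None,
        psu_col: Optional[str] = None,
    ) -> "SurveyLogit":
        """Build the design matrix from a DataFrame.

        Non-numeric predictors are expanded to treatment-coded indicator
        columns (first level as reference); an intercept is always included.
        """
        cols = [outcome] + list(predictors)
        for extra in (weight_col, strata_col, psu_col):
            if extra:
                cols.append(extra)
        sub = data[cols].dropna()
        pieces = [pd.Series(1.0, index=sub.index, name="const")]
        for name in predictors:
            col = sub[name]
            if col.dtype.kind in "biufc" and col.dtype.kind != "b":
                pieces.append(col.astype(float))
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
                pieces.append(dummies.astype(float))
        design = pd.concat(pieces, axis=1)
        return cls(
            endog=sub[outcome].to_numpy(dtype=float),
            exog=design.to_numpy(dtype=float),
            weights=sub[weight_col].to_numpy(dtype=float) if weight_col else None,
            exog_names=list(design.columns),
            strata=sub[strata_col].to_numpy() if strata_col else None,
            psu=sub[psu_col].to_numpy() if psu_col else None,
        )

    def fit(self) -> SurveyLogitResults:
        glm = sm.GLM(
            self.endog, self.exog, family=sm.families.Binomial(), freq_weights=self.weights
        )
        res = glm.fit()
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 50:
            raise RuntimeError(
                "logistic fit did not yield finite, stable coefficients "
                "(possible perfect separation)"
            )
        mu = res.fittedvalues
        w = self.weights
        X = self.exog
        info = X.T @ (X * (w * mu * (1 - mu))[:, None])
        bread = np.linalg.pinv(info)
        score_obs = X * (w * (self.endog - mu))[:, None]

        if self.strata is not None and self.psu is not None:
            meat = self._linearized_meat(score_obs)
            kind = "stratified PSU linearized"
        else:
            meat = score_obs.T @ score_obs
            kind = "sandwich (HC0)"
        cov = bread @ meat @ bread
        return SurveyLogitResults(
            params=params,
            cov=cov,
            exog_names=self.exog_names,
            n_unweighted=len(self.endog),
            n_weighted=float(np.sum(w)),
            vcov_kind=kind,
        )

    def _linearized_meat(self, score_obs: np.ndarray) -> np.ndarray:
        """Taylor linearization: between-PSU variance of weighted score totals."""
        p = score_obs.shape[1]
        meat = np.zeros((p, p))
        strata = self.strata
        for h in np.unique(strata):
            mask = strata == h
            psus = self.psu[mask]
            uniq = np.unique(psus)
            n_h = len(uniq)
            if n_h < 2:
                continue  # single-PSU stratum contributes no variance (centered at itself)
            totals = np.vstack([score_obs[mask][psus == j].sum(axis=0) for j in uniq])
            centered = totals - totals.mean(axis=0)
            meat += n_h / (n_h - 1) * (centered.T @ centered)
        return meat


@dataclass(frozen=True)
class OutcomeModelResult:
    """One fitted outcome model: OR per 10-point MNI with design-based CI."""

    outcome: str
    n_unweighted: int
    n_weighted: float
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    covariate_estimates: Mapping[str, Tuple[float, float]]
    term: str = "mni_10pt"

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower <= self.odds_ratio <= self.ci_upper):
            raise ValueError("odds ratio must lie inside its confidence interval")

    def to_dict(self) -> Dict:
        return {
            "outcome": self.outcome,
            "term": self.term,
            "n": self.n_unweighted,
            "n_weighted": self.n_weighted,
            "odds_ratio": self.odds_ratio,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "covariates": {k: {"coef": v[0], "se": v[1]} for k, v in self.covariate_estimates.items()},
        }


# -- end-to-end pipeline ---------------------------------------------------


def prepare_cohort(
    cohort: pd.DataFrame,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
    config: EligibilityConfig = EligibilityConfig(),
) -> pd.DataFrame:
    """Score a flat cohort table and attach outcomes and eligibility columns.

    ``cohort`` has one row per participant with the profile columns
    (person_id, sex, age_y, weight_kg, height_cm, smoker, pregnant,
    lactating, hypertension, activity_level), one column per nutrient with
    the two-day average intake, the recall/medication/diet flags, raw outcome
    fields (phq9_total, bmi, the five cvd_* questions, health_rating),
    covariates (race, education, healthcare_use) and survey_weight.

    Adds: target_kcal, energy_ratio, mni, mni_10pt, per-nutrient score
    columns, the four binary outcomes (y_obesity, y_health, y_depression,
    y_cvd) and eligibility flags eligible_base / eligible_<outcome>.
    """
    out = cohort.reset_index(drop=True).copy()
    scores = score_cohort(out, out, library=library, shape=shape)
    for col in scores.columns:
        if col != "person_id":
            out[col] = scores[col].to_numpy()
    out["energy_ratio"] = out["energy"].to_numpy(dtype=float) / out["target_kcal"].to_numpy()

    out["y_obesity"] = (out["bmi"] >= 30).where(out["bmi"].notna()).astype(float)
    favorable = [r.lower() for r in config.favorable_health]
    rating = out["health_rating"].astype("string").str.strip().str.lower()
    known = rating.isin(HEALTH_RATINGS)
    if (rating.notna() & ~known).any():
        bad = rating[rating.notna() & ~known].iloc[0]
        raise ValueError(f"unknown health rating {bad!r}")
    out["y_health"] = rating.isin(favorable).where(rating.notna()).astype(float)
    phq = out["phq9_total"]
    if ((phq < 0) | (phq > 27)).any():
        raise ValueError("PHQ-9 totals must be in [0, 27]")
    out["y_depression"] = (phq >= 10).where(phq.notna()).astype(float)
    cvd = out[list(CVD_QUESTIONS)]
    out["y_cvd"] = (cvd == 1).any(axis=1).where(cvd.notna().any(axis=1)).astype(float)

    for analysis in ("base",) + OUTCOMES:
        flags = eligibility_frame(out, analysis, config)
        out[f"eligible_{analysis}"] = flags["included"].to_numpy()
    return out


def fit_outcome_model(
    prepared: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    score_col: str = "mni_10pt",
    weight_col: str = "survey_weight",
    strata_col: Optional[str] = None,
    psu_col: Optional[str] = None,
    min_records: int = 50,
) -> OutcomeModelResult:
    """Survey-weighted logistic fit of one outcome on the MNI score.

    ``prepared`` comes from :func:`prepare_cohort`; records are restricted to
    the outcome's eligible subset.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    sub = prepared[prepared[f"eligible_{outcome}"]]
    if len(sub) < min_records:
        raise ValueError(
            f"only {len(sub)} eligible records for {outcome!r} (need >= {min_records})"
        )
    model = SurveyLogit.from_dataframe(
        sub,
        outcome=f"y_{outcome}",
        predictors=[score_col] + list(covariates),
        weight_col=weight_col,
        strata_col=strata_col,
        psu_col=psu_col,
    )
    res = model.fit()
    or_table = res.odds_ratios()
    row = or_table.loc[score_col]
    covs = {
        name: (float(res.params[name]), float(res.bse[name]))
        for name in res.params.index
        if name != score_col
    }
    return OutcomeModelResult(
        outcome=outcome,
        n_unweighted=res.n_unweighted,
        n_weighted=res.n_weighted,
        odds_ratio=float(row["OR"]),
        ci_lower=float(row["ci_lower"]),
        ci_upper=float(row["ci_upper"]),
        p_value=float(row["p_value"]),
        covariate_estimates=covs,
        term=score_col,
    )


def run_validation_pipeline(
    cohort: pd.DataFrame,
    day1: Optional[pd.DataFrame] = None,
    day2: Optional[pd.DataFrame] = None,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
    config: EligibilityConfig = EligibilityConfig(),
    outcomes: Sequence[str] = OUTCOMES,
    **fit_kwargs,
) -> Dict[str, OutcomeModelResult]:
    """simulate/load -> average -> score -> filter -> fit, for each outcome.

    If ``day1``/``day2`` recall tables are given they are averaged and their
    nutrient columns replace any intake columns already present in ``cohort``.
    """
    if (day1 is None) != (day2 is None):
        raise ValueError("supply both recall days or neither")
    if day1 is not None:
        avg = average_recall_frames(day1, day2)
        cohort = cohort.drop(
            columns=[c for c in avg.columns if c != "person_id" and c in cohort.columns]
        ).merge(avg, on="person_id", validate="one_to_one")
    prepared = prepare_cohort(cohort, library=library, shape=shape, config=config)
    return {oc: fit_outcome_model(prepared, oc, **fit_kwargs) for oc in outcomes}
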