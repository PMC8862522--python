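"""Synthetic cohorts with known effect sizes.

The generator emulates the structure the validation pipeline assumes: adult
profiles with NHANES-like marginals, two 24-h recall nutrient tables, dietary
survey weights, and binary health outcomes generated from a logistic link on
the 10-point MNI score. Intakes are built multiplicatively around each
person's resolved optimal levels: a per-person log-normal "diet adequacy"
latent factor, a persistent per-(person, nutrient) deviation, and day-to-day
log-normal noise. Because deviations are multiplicative around the
full-score region, adequacy identically 1 with all noise off reproduces a
perfect MNI of 100 by construction.

Everything is driven by one ``numpy.random.Generator`` seeded once per run,
so output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .energy import derive_activity_level
from .reference import ReferenceLibrary, load_reference_library
from .scoring import ScoreShape, resolve_bounds_frame, score_cohort, target_energy_frame
from .types import NO, YES, DailyIntake, IndividualProfile

__all__ = [
    "SimulationConfig",
    "simulate_profiles",
    "simulate_recalls",
    "simulate_recall_pair",
    "simulate_outcomes",
    "simulate_cohort",
]

RACE_LEVELS = (
    "mexican_american",
    "other_hispanic",
    "nh_white",
    "nh_black",
    "other_multiracial",
)
EDUCATION_LEVELS = (
    "lt_9th",
    "9_11th",
    "hs_grad",
    "some_college",
    "college_grad",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Marginals (smoker 21%, pregnancy 2.5% of women, race/education mixes)
    follow the US-adult survey composition the pipeline targets; the
    adequacy/noise parameters are calibrated so the default cohort has a
    unimodal MNI distribution with mean near 50. ``true_log_or`` holds the
    generating log odds ratios per 10 MNI points for each outcome and
    ``baseline_prevalence`` the marginal outcome rates the intercepts are
    solved for.
    """

    age_min: float = 18.0
    age_max: float = 64.0
    p_female: float = 0.5
    p_smoker: float = 0.21
    p_pregnant_female: float = 0.025
    p_lactating_female: float = 0.01
    p_hypertension: float = 0.28
    p_vigorous_work: float = 0.20
    p_vigorous_rec: float = 0.22
    p_moderate_work: float = 0.36
    p_moderate_rec: float = 0.45
    # anthropometrics: (mean, sd) by sex
    male_weight_kg: Tuple[float, float] = (88.0, 16.0)
    male_height_cm: Tuple[float, float] = (176.0, 7.5)
    female_weight_kg: Tuple[float, float] = (76.0, 18.0)
    female_height_cm: Tuple[float, float] = (162.0, 7.0)
    # latent diet-quality factor and noise (log scale)
    adequacy_mu: float = -0.5
    adequacy_sigma: float = 0.3
    nutrient_sigma: float = 1.1
    day_noise_sigma: float = 0.20
    energy_sigma: float = 0.08
    # survey weights: log-normal, mean-normalized
    weight_log_sigma: float = 0.35
    # eligibility-flag marginals
    p_recall_reliable: float = 0.97
    p_recall_typical: float = 0.93
    p_special_diet: float = 0.12
    p_meds_psychotropic: float = 0.13
    p_meds_cardiovascular: float = 0.17
    # covariate marginals
    race_probs: Tuple[float, ...] = (0.161, 0.096, 0.465, 0.172, 0.106)
    education_probs: Tuple[float, ...] = (0.079, 0.134, 0.221, 0.294, 0.272)
    p_healthcare_use: float = 0.804
    # outcome generation: logistic link on mni_10pt
    true_log_or: Mapping[str, float] = field(
        default_factory=lambda: {
            "obesity": math.log(0.92),
            "health": math.log(1.24),
            "depression": math.log(0.76),
            "cvd": math.log(0.69),
        }
    )
    baseline_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "obesity": 0.328,
            "health": 0.867,
            "depression": 0.066,
            "cvd": 0.033,
        }
    )
    # per-outcome covariate effects: log-odds per year of age (centered at 41)
    # and for female sex
    age_log_or: Mapping[str, float] = field(
        default_factory=lambda: {"obesity": 0.01, "health": -0.005, "depression": 0.0, "cvd": 0.06}
    )
    female_log_or: Mapping[str, float] = field(
        default_factory=lambda: {"obesity": 0.1, "health": 0.0, "depression": 0.3, "cvd": -0.4}
    )

    def __post_init__(self) -> None:
        for name in ("adequacy_sigma", "nutrient_sigma", "day_noise_sigma", "energy_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for outcome, p in self.baseline_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {outcome!r} must be in (0, 1)")


def _yn(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return np.where(rng.random(n) < p, YES, NO)


def simulate_profiles(
    n: int, config: SimulationConfig = SimulationConfig(), rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """One row per person: demographics, anthropometrics, conditions, flags."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    female = sex == "female"
    age = rng.uniform(config.age_min, config.age_max, n)

    weight = np.where(
        female,
        rng.normal(*config.female_weight_kg, n),
        rng.normal(*config.male_weight_kg, n),
    ).clip(40, 200)
    height = np.where(
        female,
        rng.normal(*config.female_height_cm, n),
        rng.normal(*config.male_height_cm, n),
    ).clip(130, 210)

    # pregnancy/lactation restricted to ages <= 45; rescale so the overall
    # female marginal matches the configured fraction
    frac_eligible = max(
        1e-9, (min(45.0, config.age_max) - config.age_min) / (config.age_max - config.age_min)
    )
    pregnant = (
        female & (age <= 45) & (rng.random(n) < min(1.0, config.p_pregnant_female / frac_eligible))
    )
    lactating = (
        female
        & ~pregnant
        & (age <= 45)
        & (rng.random(n) < min(1.0, config.p_lactating_female / frac_eligible))
    )

    paq = {
        "vigorous_work": _yn(rng, config.p_vigorous_work, n),
        "vigorous_rec": _yn(rng, config.p_vigorous_rec, n),
        "moderate_work": _yn(rng, config.p_moderate_work, n),
        "moderate_rec": _yn(rng, config.p_moderate_rec, n),
    }
    vig = (paq["vigorous_work"] == YES).astype(int) + (paq["vigorous_rec"] == YES).astype(int)
    mod = (paq["moderate_work"] == YES).astype(int) + (paq["moderate_rec"] == YES).astype(int)
    level = np.select([vig == 2, vig == 1, mod == 2, mod == 1], [5, 4, 3, 2], default=1)

    weights = rng.lognormal(0.0, config.weight_log_sigma, n)
    weights /= weights.mean()

    df = pd.DataFrame(
        {
            "person_id": [f"p{i:06d}" for i in range(n)],
            "sex": sex,
            "age_y": age,
            "weight_kg": weight,
            "height_cm": height,
            "smoker": rng.random(n) < config.p_smoker,
            "pregnant": pregnant,
            "lactating": lactating,
            "hypertension": rng.random(n) < config.p_hypertension,
            **paq,
            "activity_level": level,
            "race": rng.choice(RACE_LEVELS, n, p=config.race_probs),
            "education": rng.choice(EDUCATION_LEVELS, n, p=config.education_probs),
            "healthcare_use": rng.random(n) < config.p_healthcare_use,
            "survey_weight": weights,
            "recall1_reliable": rng.random(n) < config.p_recall_reliable,
            "recall2_reliable": rng.random(n) < config.p_recall_reliable,
            "recall1_typical": rng.random(n) < config.p_recall_typical,
            "recall2_typical": rng.random(n) < config.p_recall_typical,
            "special_diet": rng.random(n) < config.p_special_diet,
            "meds_psychotropic": rng.random(n) < config.p_meds_psychotropic,
            "meds_cardiovascular": rng.random(n) < config.p_meds_cardiovascular,
        }
    )
    return df


def _reference_points(
    profiles: pd.DataFrame, library: ReferenceLibrary, shape: ScoreShape
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Per-person full-score reference intake for each nutrient (+ target kcal).

    Midpoint of two-sided ranges, 1.2x the floor for adequacy-style ranges,
    half the limit for limit-style ranges.
    """
    targets = target_energy_frame(profiles)
    target_kcal = targets["target_kcal"].to_numpy()
    bounds = resolve_bounds_frame(profiles, library, shape, target_kcal=target_kcal)
    refs = {}
    for nutrient, (lower, upper) in bounds.items():
        has_l, has_u = ~np.isnan(lower), ~np.isnan(upper)
        ref = np.where(has_l & has_u, (lower + upper) / 2.0, np.where(has_l, lower * 1.2, upper * 0.5))
        refs[nutrient] = ref
    refs["energy"] = target_kcal
    return pd.DataFrame(refs, index=profiles.index), target_kcal


def simulate_recalls(
    profiles: pd.DataFrame,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two recall-day intake tables (person_id + one column per nutrient)."""
    rng = np.random.default_rng(0) if rng is None else rng
    if library is None:
        library = load_reference_library()
    refs, _ = _reference_points(profiles, library, shape)
    n = len(profiles)
    nutrients = list(refs.columns)

    adequacy = rng.lognormal(config.adequacy_mu, config.adequacy_sigma, n)
    days = []
    person_dev = np.empty((n, len(nutrients)))
    for j, nutrient in enumerate(nutrients):
        sigma = config.energy_sigma if nutrient == "energy" else config.nutrient_sigma
        person_dev[:, j] = rng.lognormal(0.0, sigma, n) if sigma > 0 else 1.0
    for _day in (1, 2):
        values = refs.to_numpy() * adequacy[:, None] * person_dev
        if config.day_noise_sigma > 0:
            values = values * rng.lognormal(0.0, config.day_noise_sigma, values.shape)
        day = pd.DataFrame(values, columns=nutrients)
        day.insert(0, "person_id", profiles["person_id"].to_numpy())
        days.append(day)
    return days[0], days[1]


def simulate_recall_pair(
    profile: IndividualProfile,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
) -> Tuple[DailyIntake, DailyIntake]:
    """Scalar convenience: two simulated recall days for one profile."""
    if profile.activity_level is not None:
        level = profile.activity_level
    elif profile.activity is not None:
        level = derive_activity_level(profile.activity)
    else:
        level = 1
    row = pd.DataFrame(
        {
            "person_id": [profile.person_id],
            "sex": [profile.sex],
            "age_y": [profile.age_y],
            "weight_kg": [profile.weight_kg],
            "height_cm": [profile.height_cm],
            "smoker": [profile.smoker],
            "pregnant": [profile.pregnant],
            "lactating": [profile.lactating],
            "hypertension": [profile.hypertension],
            "activity_level": [level],
        }
    )
    d1, d2 = simulate_recalls(row, config, rng, library, shape)
    to_intake = lambda df: DailyIntake(
        person_id=profile.person_id,
        amounts={c: float(df[c].iloc[0]) for c in df.columns if c != "person_id"},
    )
    return to_intake(d1), to_intake(d2)


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) == prevalence."""

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp))) - prevalence

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"prevalence {prevalence} unattainable for given linear predictor")
    return brentq(gap, lo, hi, xtol=1e-10)


def simulate_outcomes(
    profiles: pd.DataFrame,
    mni_10pt: np.ndarray,
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Binary outcomes from the logistic link, plus consistent raw fields.

    Raw fields (phq9_total, bmi, the five CVD questions, health_rating) are
    synthesized to dichotomize back to the generated binary outcome, so the
    pipeline's dichotomizers are exercised end to end. The synthetic BMI is
    deliberately decoupled from the profile's weight/height (which drive the
    energy target) so the outcome's logistic link stays exact.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(profiles)
    mni_10pt = np.asarray(mni_10pt, dtype=float)
    age_c = profiles["age_y"].to_numpy(dtype=float) - 41.0
    female = (profiles["sex"].to_numpy() == "female").astype(float)

    y: Dict[str, np.ndarray] = {}
    for outcome, beta in config.true_log_or.items():
        lp = (
            beta * mni_10pt
            + config.age_log_or[outcome] * age_c
            + config.female_log_or[outcome] * female
        )
        alpha = _solve_intercept(lp, config.baseline_prevalence[outcome])
        y[outcome] = (rng.random(n) < expit(alpha + lp)).astype(int)

    out = pd.DataFrame({"person_id": profiles["person_id"].to_numpy()})

    if "depression" in y:
        dep = y["depression"].astype(bool)
        phq = rng.integers(0, 10, n)
        phq[dep] = 10 + np.minimum(rng.poisson(4.0, int(dep.sum())), 17)
        out["phq9_total"] = phq

    if "obesity" in y:
        obese = y["obesity"].astype(bool)
        bmi = rng.uniform(19.0, 29.9, n)
        bmi[obese] = 30.0 + rng.gamma(2.0, 2.5, int(obese.sum()))
        out["bmi"] = np.floor(bmi * 10 + 0.5) / 10.0

    if "cvd" in y:
        cvd = y["cvd"].astype(bool)
        answers = np.zeros((n, 5), dtype=int)
        k = int(cvd.sum())
        if k:
            ans = (rng.random((k, 5)) < 0.35).astype(int)
            none = ans.sum(axis=1) == 0
            ans[none, 3] = 1  # default to heart attack when no question fired
            answers[cvd] = ans
        for j, col in enumerate(
            ("cvd_chf", "cvd_chd", "cvd_angina", "cvd_heart_attack", "cvd_stroke")
        ):
            out[col] = answers[:, j]

    if "health" in y:
        favorable = y["health"].astype(bool)
        rating = rng.choice(["fair", "poor"], n, p=[0.75, 0.25]).astype(object)
        rating[favorable] = rng.choice(
            ["excellent", "very good", "good"], int(favorable.sum()), p=[0.25, 0.40, 0.35]
        )
        out["health_rating"] = rating
    return out


def simulate_cohort(
    n: int,
    seed: int,
    config: SimulationConfig = SimulationConfig(),
    library: Optional[ReferenceLibrary] = None,
    shape: ScoreShape = ScoreShape(),
) -> Dict[str, pd.DataFrame]:
    """Full synthetic dataset: profiles, two recall days, flat cohort table.

    The flat ``cohort`` table carries the averaged intakes plus all profile,
    flag, covariate and raw-outcome columns — exactly what
    :func:`mni.pipeline.prepare_cohort` consumes. Outcomes are generated from
    the MNI computed on the averaged recalls, i.e. on the same quantity the
    pipeline later reconstructs.
    """
    rng = np.random.default_rng(seed)
    if library is None:
        library = load_reference_library()
    profiles = simulate_profiles(n, config, rng)
    day1, day2 = simulate_recalls(profiles, config, rng, library, shape)
    avg = day1.set_index("person_id").add(day2.set_index("person_id")).div(2.0).reset_index()
    scores = score_cohort(profiles, avg, library, shape)
    outcomes = simulate_outcomes(profiles, scores["mni_10pt"].to_numpy(), config, rng)
    cohort = profiles.merge(avg, on="person_id").merge(outcomes, on="person_id")
    return {"profiles": profiles, "day1": day1, "day2": day2, "cohort": cohort}
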