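# Methods

## Scope

`mni` computes a personalized nutrient-adequacy index and reproduces the
survey-style validation such an index is judged with. Three layers:

1. **Reference resolution** — a versioned DRI snapshot (CSV tables shipped
   with the package) mapped onto one `[L, U]` range per nutrient per person.
2. **Scoring** — piecewise-linear per-nutrient scores, an energy-agreement
   score against a Mifflin-St Jeor target, geometric-mean aggregation to a
   0–100 index.
3. **Validation pipeline** — two-recall averaging, eligibility filtering,
   outcome dichotomization, survey-weighted logistic regression; plus a
   synthetic-cohort generator with a known logistic link for end-to-end
   testing.

## Reference library

The snapshot (`src/mni/data/`, version `dri-snapshot-2026.09`) stores one row
per nutrient × life-stage group with columns
`nutrient, sex, age_min, age_max, pregnant, lactating, lower, upper, basis,
unit`. Lower bounds are RDAs or AIs; upper bounds on those rows are the
tolerable upper intake levels (UL); macronutrient bands are AMDRs in % of
energy; saturated fat (10 %E), cholesterol (300 mg), total sugars (10 %E,
the added-sugar guideline applied conservatively when only total sugars are
measured), alcohol (28 g/day men, 14 g/day women, zero under 19) and caffeine
(FDA 400 mg/day; 100 mg under 19) are guideline limits. Coverage: ages 9–70
both sexes plus pregnancy/lactation rows (19–50). Age groups are integer DRI
brackets, so a row covers `[age_min, age_max + 1)` — an 18.5-year-old belongs
to the 14–18 group.

Decisions where the DRI tables leave gaps:

- **Monounsaturated / polyunsaturated fat** have no DRI values. The snapshot
  carries declared bands (MUFA 10–20 %E, PUFA 5–10 %E) in line with common
  dietary guidance; they are data, not code, and replaceable.
- **Protein** is stored as g/kg body weight (RDA 0.8 g/kg adults, 1.1
  pregnant, 1.3 lactating). The range-table schema keeps one unit per row, so
  the protein AMDR cap is applied at conversion time as 35 % of target energy
  (configurable via `ScoreShape.protein_energy_cap_pct`).
- **Hypertension** lowers the sodium upper bound to 1500 mg (the lower
  sodium guideline for at-risk adults); **smoking** raises the vitamin C
  floor by the DRI smoker increment of 35 mg/day. Both live in
  `modifiers.csv` and are applied after life-stage lookup in a fixed order
  (smoker → hypertension → pregnancy → lactation → user-defined).
- **Pregnancy/lactation** are handled as dedicated life-stage rows, as in the
  DRI tables, with a deterministic fallback chain (lactation row, else
  pregnancy row, else general row) for nutrients without dedicated rows.
- The pediatric zinc group follows the published DRI bracket 9–13 (8–23 mg);
  `load_reference_library(pediatric_zinc_group="9-14")` loads a variant with
  the group widened to 9–14 for comparability with descriptions that use
  that grouping.

Resolution is a pure function of (profile, library): ranges in %E or g/kg
units are only converted to absolute g/day in the scoring layer, using the
person's **target** energy (not the observed diet), so resolved ranges are
diet-independent and the "perfect diet" is well defined.

## Score shape

The penalty form outside the optimal range is a declared modeling choice,
exposed in `ScoreShape`:

| parameter | default | meaning |
|---|---|---|
| `rise_anchor` | 0 | intake at which the deficiency ramp starts from 0 |
| `fall_span` | 2.0 | score reaches 0 at `fall_span × U` above the range |
| `floor` | 0.01 | minimum per-nutrient score entering the geometric mean |
| `energy_band` | 0.10 | half-width of the full-score energy band (± of target) |
| `protein_energy_cap_pct` | 35 | protein upper bound as % of target energy |

Boundary semantics: intakes exactly at `L` or `U` score 1.0. A zero upper
limit (adolescent alcohol) scores 1 only at exactly zero intake. The floor
prevents one absent nutrient from forcing the composite to 0; consequently
the worst possible diet scores exactly `100 × floor = 1.0`, while an
*all-zero* diet scores `100 × floor^(29/34) ≈ 1.97`, because zero intake of
the five upper-bound-only nutrients is genuinely optimal and scores 1 — an
excess limit is not an intake requirement.

The composite is `100 · exp(mean(log max(sᵢ, floor)))` over the 33 non-energy
nutrients plus the energy score; it is permutation-invariant, bounded by
`100 × [min floored score, max score]`, and never exceeds the arithmetic
mean. Both the scalar path (`compute_mni`) and the vectorized cohort path
(`score_cohort`) are tested to agree to 1e-9.

## Energy targets

BMR from Mifflin-St Jeor (10W + 6.25H − 5A + 5 male / −161 female; constants
in `mni.energy`, not scattered), times a 5-level activity multiplier
(1.20, 1.375, 1.55, 1.725, 1.90). The level derives from four yes/no items:
both vigorous → 5, one vigorous → 4, both moderate → 3, one moderate → 2,
else 1; missing items count as "no" (the catch-all) and set a warning flag on
the `EnergyTarget`. The plausibility filter keeps records with
0.33 < observed/target < 3.0 (strict), applied by default to the two-day
average (`EligibilityConfig.filter_on_average`).

## Validation pipeline

Eligibility: age window (default inclusive 18–64, configurable to 18–65),
both recalls reliable *and* typical, no special diet, energy filter; then
outcome-specific exclusions — psychotropic medication (depression),
cardiovascular medication (CVD), pregnancy (obesity) — and `missing_data`
for absent outcome fields. All failed codes are reported per record; the
audit table offers both overlapping counts and a waterfall mode (first failed
filter per record) whose counts plus the included count sum exactly to the
input size.

Dichotomization: PHQ-9 total ≥ 10 (the analysis-style threshold; the looser
prose reading "above 10" is not used); BMI = kg/m² rounded **half-up** to one
decimal, obese at ≥ 30; CVD = yes to any of congestive heart failure,
coronary heart disease, angina, heart attack, stroke (missing only if all
five are missing); favorable self-rated health = excellent/very good/good
(the descriptive-table grouping excellent/very good is available via
`EligibilityConfig.favorable_health`).

Regression: `SurveyLogit` maximizes the weight-multiplied log-likelihood
(statsmodels GLM with frequency weights supplies the point estimates) and
reports a probability-weight sandwich covariance
`B⁻¹ (Σ wᵢ²uᵢuᵢᵀ) B⁻¹`; this matches R's `sandwich::vcovHC(type = "HC0")` on
a weighted quasibinomial GLM to 1e-6 (frozen oracle test). When stratum and
PSU columns are supplied, the middle term is Taylor-linearized over weighted
PSU score totals within strata with the `n_h/(n_h−1)` factor — an
approximation to full survey procedures, documented as such. Exposure is the
10-point MNI (`mni/10`); covariates default to age, sex, race/ethnicity (5
levels), education (5 levels) and healthcare use, expanded treatment-coded.
`standardize_scores` provides (optionally weighted) centering/scaling for
cross-index comparisons.

## Synthetic cohorts

The generator is test scaffolding with declared, not estimated,
distributions: ages uniform on the study window; sex Bernoulli(0.5); smoking
21%, pregnancy 2.5% of women, race/education/healthcare marginals matching
the US-adult survey composition the pipeline targets. Intake for person *p*,
nutrient *j*, day *d* is

```
x_pjd = ref_pj × A_p × exp(ε_pj) × exp(δ_pjd)
```

where `ref_pj` is the midpoint of the resolved range (1.2L or 0.5U for
one-sided ranges), `A_p ~ lognormal(−0.5, 0.3)` is the latent diet-quality
factor, `ε_pj ~ N(0, 1.1²)` a persistent per-nutrient deviation and
`δ_pjd ~ N(0, 0.2²)` day noise (energy uses a tighter σ = 0.08 so the
energy-plausibility filter passes at realistic rates, ~97%). These values
were calibrated once so the default cohort has a unimodal MNI distribution
with mean ≈ 50 (sd ≈ 10), then frozen. Outcomes follow
`P(Y=1) = expit(α + β·MNI₁₀ + covariate terms)` with β the configured log-OR
per 10 points (defaults 0.92/1.24/0.76/0.69 for obesity/health/depression/
CVD) and α solved by root-finding so the marginal prevalence matches the
configured rate (33%/87%/6.6%/3.3%). Raw fields (PHQ-9 totals, BMI, the five
CVD answers, health ratings) are synthesized to dichotomize back to the
generated binaries so the pipeline is exercised end to end; the synthetic BMI
is deliberately decoupled from the profile's weight/height (which drive the
energy target) to keep the logistic link exact.

What passing tests therefore show: the scoring arithmetic, filters and
design-based estimation are correct and unbiased *under this generative
model*. What they do not show: robustness to real recall measurement error,
correlated nutrient patterns from actual foods, informative sampling designs,
or confounding structures absent from the generator.

## Problem sizes and numerical choices

The parameter-recovery study uses 200 replicates of n = 5000 cohorts (about
two minutes total on one core thanks to the vectorized scorer); bias in the
fitted log-OR is required to stay below 0.02 for each outcome and the nominal
95% CI for the depression OR to cover at roughly its nominal rate. A single
full simulate → score → fit run at n = 5000 takes well under two seconds.
Degenerate inputs fail loudly: outcome without variation, perfect separation
(coefficients exploding past ±50), constant score vectors in
`standardize_scores`, negative intakes, and reference rows that overlap or
leave an adult age uncovered are all hard errors. Ties at range boundaries
score 1.0; BMI rounding is half-up, as documented.

## Known limitations

- The DRI snapshot covers ages 9–70; infants, young children and 70+ adults
  are out of scope, as are supplement-sourced nutrients and iodine
  (no dietary-iodine totals in the target data).
- The decay shape outside the optimal range (linear, `fall_span` 2.0, floor
  0.01, ±10% energy band) is a declared default, not an estimated quantity;
  sensitivity to it should be explored via `ScoreShape`.
- Survey variance is a sandwich/linearized approximation, not a full
  replicate-weight implementation.
- Total-sugar intakes are scored against an added-sugar-style limit when only
  totals are measured — conservative by construction and replaceable in the
  snapshot.
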