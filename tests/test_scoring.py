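"""Piecewise nutrient scores and the geometric-mean composite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mni.energy import target_energy
from mni.reference import ReferenceRange, resolve_reference_ranges
from mni.scoring import (
    MNIScorer,
    ScoreShape,
    absolute_bounds,
    aggregate_scores,
    compute_mni,
    full_score_intake,
    score_cohort,
    score_energy,
    score_nutrient,
    to_ten_point,
)
from mni.simulate import SimulationConfig, simulate_profiles, simulate_recalls
from mni.types import DailyIntake, IndividualProfile

ZINC_9_13 = ReferenceRange(nutrient="zinc", lower=8, upper=23, basis="RDA", unit="mg")
POTASSIUM = ReferenceRange(nutrient="potassium", lower=4700, upper=None, basis="AI", unit="mg")
CAFFEINE = ReferenceRange(nutrient="caffeine", lower=None, upper=400, basis="FDA-limit", unit="mg")


def adult(**kwargs):
    base = dict(
        person_id="p", sex="male", age_y=30.0, weight_kg=80.0, height_cm=178.0, activity_level=3
    )
    base.update(kwargs)
    return IndividualProfile(**base)


class TestScoreNutrient:
    @pytest.mark.parametrize(
        "intake,expected",
        [
            (8, 1.0),  # full score exactly at the floor of the band
            (23, 1.0),  # and at its cap
            (15, 1.0),
            (0, 0.0),  # rise starts at zero intake
            (4, 0.5),  # halfway up the rise
            (30, (46 - 30) / (46 - 23)),  # on the fall, zero at 2x upper
            (46, 0.0),
            (60, 0.0),  # clamped beyond the fall
        ],
    )
    def test_band_range_piecewise(self, intake, expected):
        assert score_nutrient(intake, ZINC_9_13) == pytest.approx(expected)

    def test_above_cap_scores_below_one(self):
        assert score_nutrient(24, ZINC_9_13) < 1.0

    @pytest.mark.parametrize("intake,expected", [(4700, 1.0), (5000, 1.0), (2350, 0.5), (0, 0.0)])
    def test_floor_only_range(self, intake, expected):
        assert score_nutrient(intake, POTASSIUM) == pytest.approx(expected)

    @pytest.mark.parametrize("intake,expected", [(0, 1.0), (400, 1.0), (600, 0.5), (800, 0.0)])
    def test_limit_only_range(self, intake, expected):
        assert score_nutrient(intake, CAFFEINE) == pytest.approx(expected)

    def test_zero_limit_scores_one_only_at_zero(self):
        rng = ReferenceRange(nutrient="alcohol", lower=None, upper=0, basis="FDA-limit", unit="g")
        assert score_nutrient(0, rng) == 1.0
        assert score_nutrient(0.1, rng) == 0.0

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            score_nutrient(-1, ZINC_9_13)

    @settings(max_examples=100, derandomize=True)
    @given(intake=st.floats(min_value=0, max_value=1000))
    def test_scores_bounded_and_unimodal_toward_band(self, intake):
        s = score_nutrient(intake, ZINC_9_13)
        assert 0.0 <= s <= 1.0
        # stepping toward the band never decreases the score
        if intake < 8:
            assert score_nutrient(min(intake + 1, 8), ZINC_9_13) >= s
        elif intake > 23:
            assert score_nutrient(max(intake - 1, 23), ZINC_9_13) >= s


class TestScoreEnergy:
    def test_at_target_full_score(self):
        assert score_energy(2000, 2000.0) == 1.0

    def test_band_edges_full_score(self):
        assert score_energy(1800, 2000.0) == 1.0
        assert score_energy(2200, 2000.0) == 1.0

    def test_zero_intake_scores_zero(self):
        assert score_energy(0, 2000.0) == 0.0

    def test_flanks_monotone_in_relative_error(self):
        scores = [score_energy(2000 * r, 2000.0) for r in (1.0, 1.2, 1.5, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        low = [score_energy(2000 * r, 2000.0) for r in (1.0, 0.8, 0.5, 0.2)]
        assert all(a >= b for a, b in zip(low, low[1:]))


class TestAggregate:
    def test_two_component_toy(self):
        assert aggregate_scores([0.25, 1.0]) == pytest.approx(50.0)

    def test_all_at_floor(self):
        assert aggregate_scores([0.0, 0.0, 0.0]) == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_product(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(34)
        shape = ScoreShape()
        floored = np.maximum(scores, shape.floor)
        product = 1.0
        for s in floored:
            product *= s
        expected = 100.0 * product ** (1.0 / len(floored))
        assert aggregate_scores(scores) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_extremes_and_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        scores = rng.random(34)
        shape = ScoreShape()
        floored = np.maximum(scores, shape.floor)
        composite = aggregate_scores(scores)
        assert composite <= 100 * floored.max() + 1e-12
        assert composite >= 100 * floored.min() - 1e-12
        assert composite <= 100 * floored.mean() + 1e-12

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            aggregate_scores([0.5, 1.2])


class TestComputeMNI:
    def test_full_score_diet_is_exactly_100(self, library):
        p = adult()
        res = compute_mni(full_score_intake(p, library), p, library)
        assert res.mni == 100.0
        assert res.mni_10pt == 10.0
        assert all(s == 1.0 for s in res.per_nutrient.values())
        assert res.library_version == library.version

    def test_worst_diet_is_exactly_100x_floor(self, library, shape):
        p = adult()
        target = target_energy(p)
        resolved = resolve_reference_ranges(p, library)
        amounts = {}
        for code, rng in resolved.items():
            lo, up = absolute_bounds(code, rng, p.weight_kg, target.target_kcal, shape)
            amounts[code] = 0.0 if lo is not None else shape.fall_span * up
        amounts["energy"] = 0.0
        res = compute_mni(DailyIntake("p", amounts), p, library)
        assert res.mni == pytest.approx(100.0 * shape.floor, rel=1e-12)

    def test_all_zero_diet_keeps_limit_nutrients_perfect(self, library, shape):
        # zero intake scores 1.0 for upper-bound-only nutrients, so the
        # composite sits above the floor: 100 * floor^(29/34)
        p = adult()
        zero = DailyIntake("p", {c: 0.0 for c in library.nutrients})
        res = compute_mni(zero, p, library)
        limit_only = [c for c, s in res.per_nutrient.items() if s == 1.0]
        assert len(limit_only) == 5
        assert res.mni == pytest.approx(100.0 * shape.floor ** (29 / 34), rel=1e-9)

    def test_nutrient_order_invariance(self, library):
        p = adult()
        intake = full_score_intake(p, library)
        jitter = {k: v * 0.7 for k, v in intake.amounts.items()}
        forward = compute_mni(DailyIntake("p", jitter), p, library)
        backward = compute_mni(
            DailyIntake("p", dict(reversed(list(jitter.items())))), p, library
        )
        assert forward.mni == backward.mni

    def test_moving_one_nutrient_toward_band_never_lowers_composite(self, library, shape):
        p = adult()
        target = target_energy(p)
        resolved = resolve_reference_ranges(p, library)
        base_amounts = {k: v * 0.5 for k, v in full_score_intake(p, library).amounts.items()}
        base = compute_mni(DailyIntake("p", base_amounts), p, library).mni
        for code in ("zinc", "vitamin_c", "potassium", "fiber"):
            lo, up = absolute_bounds(
                code, resolved[code], p.weight_kg, target.target_kcal, shape
            )
            toward = dict(base_amounts)
            toward[code] = (toward[code] + lo) / 2  # halfway toward the floor
            assert compute_mni(DailyIntake("p", toward), p, library).mni >= base

    def test_missing_nutrient_is_an_error_unless_imputed(self, library):
        p = adult()
        amounts = dict(full_score_intake(p, library).amounts)
        amounts.pop("zinc")
        with pytest.raises(KeyError, match="zinc"):
            compute_mni(DailyIntake("p", amounts), p, library)
        with pytest.warns(UserWarning, match="zinc"):
            res = compute_mni(DailyIntake("p", amounts), p, library, impute_missing=True)
        assert res.imputed_nutrients == ("zinc",)

    def test_smoking_lowers_score_for_identical_diet(self, library):
        # same foods, average vitamin C: the smoker's raised floor bites
        p = adult()
        intake_amounts = dict(full_score_intake(p, library).amounts)
        intake_amounts["vitamin_c"] = 100.0  # above 90 (nonsmoker), below 125 (smoker)
        nonsmoker = compute_mni(DailyIntake("p", intake_amounts), p, library)
        smoker = compute_mni(DailyIntake("p", intake_amounts), adult(smoker=True), library)
        assert smoker.per_nutrient["vitamin_c"] < nonsmoker.per_nutrient["vitamin_c"] == 1.0
        assert smoker.mni < nonsmoker.mni


class TestTenPoint:
    @pytest.mark.parametrize("mni,expected", [(100, 10.0), (0, 0.0), (52.8, 5.28)])
    def test_rescaling(self, mni, expected):
        assert to_ten_point(mni) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-1, 101])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            to_ten_point(bad)


class TestCohortScoring:
    def test_vectorized_agrees_with_scalar(self, library, shape):
        cfg = SimulationConfig()
        rng = np.random.default_rng(123)
        profiles = simulate_profiles(50, cfg, rng)
        day1, _ = simulate_recalls(profiles, cfg, rng, library, shape)
        table = score_cohort(profiles, day1, library, shape)
        from mni.io import profiles_from_frame

        for i, profile in enumerate(profiles_from_frame(profiles)):
            row = day1.iloc[i]
            intake = DailyIntake(
                person_id=profile.person_id,
                amounts={c: float(row[c]) for c in day1.columns if c != "person_id"},
            )
            scalar = compute_mni(intake, profile, library, shape)
            assert table["mni"].iloc[i] == pytest.approx(scalar.mni, abs=1e-9)
            assert table["target_kcal"].iloc[i] == pytest.approx(scalar.target_kcal, abs=1e-9)
            for code, s in scalar.per_nutrient.items():
                assert table[f"score_{code}"].iloc[i] == pytest.approx(s, abs=1e-12)

    def test_scorer_object_roundtrip(self, library):
        scorer = MNIScorer(library=library)
        p = adult()
        res = scorer.score(full_score_intake(p, library), p)
        assert res.mni == 100.0

    def test_missing_intake_column_rejected(self, library):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        profiles = simulate_profiles(5, cfg, rng)
        day1, _ = simulate_recalls(profiles, cfg, rng)
        with pytest.raises(KeyError, match="zinc"):
            score_cohort(profiles, day1.drop(columns=["zinc"]), library)
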