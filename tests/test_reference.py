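"""Reference library: loading, life-stage lookup, condition modifiers."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mni.reference import (
    LifeStageKey,
    ModifierRule,
    NutrientSpec,
    ReferenceDataError,
    ReferenceLibrary,
    ReferenceRange,
    load_reference_library,
    resolve_reference_ranges,
)
from mni.types import IndividualProfile


def profile(**kwargs):
    base = dict(
        person_id="p", sex="male", age_y=30.0, weight_kg=80.0, height_cm=178.0, activity_level=2
    )
    base.update(kwargs)
    return IndividualProfile(**base)


class TestLibraryContents:
    def test_default_library_has_34_nutrients(self, library):
        assert len(library.nutrients) == 34

    def test_category_breakdown(self, library):
        counts = {}
        for spec in library.nutrients.values():
            counts[spec.category] = counts.get(spec.category, 0) + 1
        assert counts == {"macronutrient": 9, "vitamin": 12, "mineral": 10, "other": 3}

    def test_zinc_preadolescent_range(self, library):
        rng = library.lookup("zinc", "female", 10)
        assert (rng.lower, rng.upper) == (8.0, 23.0)
        assert library.lookup("zinc", "male", 12) == rng

    def test_caffeine_adult_limit_only(self, library):
        rng = library.lookup("caffeine", "male", 40)
        assert rng.lower is None and rng.upper == 400.0

    def test_potassium_adult_floor_only(self, library):
        rng = library.lookup("potassium", "male", 30)
        assert rng.lower == 4700.0 and rng.upper is None

    def test_lactation_specific_rows(self, library):
        assert library.lookup("potassium", "female", 30, lactating=True).lower == 5100.0
        assert library.lookup("selenium", "female", 30, lactating=True).lower == 70.0
        assert library.lookup("iron", "female", 30, pregnant=True).lower == 27.0

    def test_pregnancy_falls_back_to_general_female_row(self, library):
        # carbohydrate has no pregnancy-specific band
        assert library.lookup("carbohydrate", "female", 30, pregnant=True) == library.lookup(
            "carbohydrate", "female", 30
        )

    def test_age_18_belongs_to_adolescent_group(self, library):
        assert library.lookup("zinc", "male", 18.5).lower == 11.0
        assert library.lookup("fiber", "female", 18.0).lower == 26.0

    def test_pediatric_zinc_group_variant(self):
        default = load_reference_library()
        variant = load_reference_library(pediatric_zinc_group="9-14")
        assert default.lookup("zinc", "male", 14).lower == 11.0
        assert variant.lookup("zinc", "male", 14).lower == 8.0
        assert variant.lookup("zinc", "male", 15.5).lower == 11.0

    def test_load_is_idempotent(self, library):
        again = load_reference_library()
        assert again.version == library.version
        assert again.rows_frame().equals(library.rows_frame())

    def test_lookup_outside_coverage_names_nutrient_and_age(self, library):
        with pytest.raises(ReferenceDataError, match="zinc.*age 85"):
            library.lookup("zinc", "male", 85)


class TestResolution:
    def test_resolves_all_non_energy_nutrients(self, library):
        resolved = resolve_reference_ranges(profile(), library)
        assert len(resolved) == 33
        assert "energy" not in resolved

    def test_nonsmoker_potassium(self, library):
        rng = resolve_reference_ranges(profile(), library)["potassium"]
        assert rng.lower == 4700.0 and rng.upper is None

    def test_smoker_vitamin_c_increment(self, library):
        base = resolve_reference_ranges(profile(), library)["vitamin_c"]
        smoker = resolve_reference_ranges(profile(smoker=True), library)["vitamin_c"]
        assert smoker.lower - base.lower == 35.0

    def test_hypertension_lowers_sodium_cap(self, library):
        base = resolve_reference_ranges(profile(), library)["sodium"]
        hyp = resolve_reference_ranges(profile(hypertension=True), library)["sodium"]
        assert base.upper == 2300.0 and hyp.upper == 1500.0

    def test_irrelevant_fields_do_not_change_ranges(self, library):
        a = resolve_reference_ranges(profile(height_cm=150.0, weight_kg=50.0), library)
        b = resolve_reference_ranges(profile(height_cm=200.0, weight_kg=120.0), library)
        assert a == b

    def test_resolution_is_pure(self, library):
        p = profile(sex="female", smoker=True, hypertension=True)
        assert resolve_reference_ranges(p, library) == resolve_reference_ranges(p, library)

    @settings(max_examples=50, derandomize=True)
    @given(
        sex=st.sampled_from(["male", "female"]),
        age=st.floats(min_value=18, max_value=64.9),
        smoker=st.booleans(),
        hypertension=st.booleans(),
        pregnant=st.booleans(),
    )
    def test_every_adult_profile_gets_valid_ranges(self, sex, age, smoker, hypertension, pregnant):
        library = load_reference_library()
        p = profile(sex=sex, age_y=age, smoker=smoker, hypertension=hypertension,
                    pregnant=pregnant and sex == "female")
        resolved = resolve_reference_ranges(p, library)
        assert len(resolved) == 33
        for rng in resolved.values():
            assert rng.lower is not None or rng.upper is not None
            if rng.lower is not None and rng.upper is not None:
                assert rng.lower <= rng.upper


class TestValidation:
    def _spec(self, code="x", direction="target"):
        return NutrientSpec(code, code, "mg", "mineral", direction)

    def _row(self, lo, hi, **key):
        base = dict(sex="male", age_min_y=18, age_max_y=70)
        base.update(key)
        return (
            LifeStageKey(**base),
            ReferenceRange(nutrient="x", lower=lo, upper=hi, basis="RDA", unit="mg"),
        )

    def test_overlapping_life_stage_rows_rejected(self):
        rows = [
            self._row(1, 5, age_min_y=18, age_max_y=40),
            self._row(2, 6, age_min_y=40, age_max_y=70),
            self._row(1, 5, sex="female"),
        ]
        with pytest.raises(ReferenceDataError, match="overlap"):
            ReferenceLibrary("v", [self._spec()], rows)

    def test_missing_adult_coverage_names_nutrient(self):
        rows = [self._row(1, 5), self._row(1, 5, sex="female", age_max_y=40)]
        with pytest.raises(ReferenceDataError, match="'x'.*female"):
            ReferenceLibrary("v", [self._spec()], rows)

    def test_invalid_range_rejected(self):
        with pytest.raises(ReferenceDataError, match="lower"):
            ReferenceRange(nutrient="x", lower=5, upper=2, basis="RDA", unit="mg")
        with pytest.raises(ReferenceDataError):
            ReferenceRange(nutrient="x", lower=None, upper=None, basis="RDA", unit="mg")

    def test_modifier_cannot_invert_range(self, library):
        bad = ModifierRule(
            condition="user-defined", nutrient="zinc", bound="lower", action="set", amount=999.0
        )
        with pytest.raises(ReferenceDataError):
            resolve_reference_ranges(profile(), library, extra_modifiers=[bad])

    def test_modifier_order_is_deterministic(self, library):
        # two user-defined rules on the same bound apply in listed order
        r1 = ModifierRule("user-defined", "zinc", "upper", "set", 30.0)
        r2 = ModifierRule("user-defined", "zinc", "upper", "add", 5.0)
        out = resolve_reference_ranges(profile(), library, extra_modifiers=[r1, r2])
        assert out["zinc"].upper == 35.0

    def test_library_rejects_duplicate_codes(self):
        with pytest.raises(ReferenceDataError, match="duplicate"):
            ReferenceLibrary(
                "v",
                [self._spec(), self._spec()],
                [self._row(1, 5), self._row(1, 5, sex="female")],
            )
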