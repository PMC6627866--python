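import pytest

from sugarsteps import (
    Category,
    FoodDB,
    FoodFlags,
    FoodItem,
    Kind,
    NutrientProfile,
    ProcedureConfig,
    ValidationError,
    assign_and_estimate,
    bread_rule,
    composite_content,
    composite_step,
    fructose_subtraction,
    step_distribution,
)
from sugarsteps.sugar_steps import distribution_from_counts


def single(iid, category, total, mono=None, fructose=None, flags=None,
           counterpart=None, energy=None):
    mono = total / 2 if mono is None else mono
    return FoodItem(
        item_id=iid,
        name=iid,
        kind=Kind.SINGLE,
        category=category,
        profile=NutrientProfile(
            mono, total - mono, total, 17 * total if energy is None else energy, fructose
        ),
        flags=flags or FoodFlags(),
        unsweetened_counterpart_id=counterpart,
    )


def estimate_one(item, config=None, extra=()):
    items = {item.item_id: item}
    for it in extra:
        items[it.item_id] = it
    db = FoodDB(items, {})
    return assign_and_estimate(db, config)[item.item_id]


class TestSingleItemSteps:
    def test_cola_all_added(self):
        est = estimate_one(
            single("cola", Category.BEVERAGE_SOFT, 10.6, flags=FoodFlags(sugars_all_added=True))
        )
        assert (est.step_added, est.step_free) == (3, 3)
        assert est.added_sugars == pytest.approx(10.6)
        assert est.free_sugars == pytest.approx(10.6)

    def test_unsweetened_orange_juice_free_only(self):
        est = estimate_one(single("oj", Category.JUICE_FRUIT, 9.0))
        assert (est.step_added, est.step_free) == (2, 3)
        assert est.added_sugars == 0.0
        assert est.free_sugars == pytest.approx(9.0)

    def test_honey_excluded_from_added_included_in_free(self):
        est = estimate_one(single("honey", Category.HONEY, 80.0))
        assert est.added_sugars == 0.0
        assert est.free_sugars == pytest.approx(80.0)

    def test_honey_config_switch_counts_added(self):
        est = estimate_one(
            single("honey", Category.HONEY, 80.0), ProcedureConfig(honey_in_added=True)
        )
        assert est.added_sugars == pytest.approx(80.0)

    def test_vegetable_juice_excluded_from_both(self):
        est = estimate_one(single("carrot_juice", Category.JUICE_VEGETABLE, 6.0))
        assert (est.added_sugars, est.free_sugars) == (0.0, 0.0)
        est2 = estimate_one(
            single("carrot_juice", Category.JUICE_VEGETABLE, 6.0),
            ProcedureConfig(vegetable_juice_in_free=True),
        )
        assert est2.free_sugars == pytest.approx(6.0)

    def test_zero_sugars_is_step_one(self):
        est = estimate_one(single("meat", Category.MEAT_FISH_PLAIN, 0.0))
        assert (est.step_added, est.step_free) == (1, 1)
        assert (est.added_sugars, est.free_sugars) == (0.0, 0.0)

    def test_counterpart_subtraction(self):
        plain = single("yog_plain", Category.DAIRY_PLAIN, 4.5)
        sweet = single("yog_sweet", Category.DAIRY_SWEETENED, 12.0, counterpart="yog_plain")
        est = estimate_one(sweet, extra=[plain])
        assert (est.step_added, est.step_free) == (5, 5)
        assert est.added_sugars == pytest.approx(7.5)
        assert est.free_sugars == pytest.approx(7.5)

    def test_fructose_route(self):
        item = single(
            "muesli", Category.CEREAL_BREAKFAST, 10.0, mono=6.0, fructose=3.0,
            flags=FoodFlags(contains_fruit_or_veg=True),
        )
        est = estimate_one(item)
        assert (est.step_added, est.step_free) == (6, 6)
        assert est.added_sugars == pytest.approx(7.0)

    def test_override_step7(self):
        cfg = ProcedureConfig(override_map={"dish": (4.0, 6.0)})
        est = estimate_one(single("dish", Category.OTHER_SINGLE, 8.0), cfg)
        assert (est.step_added, est.step_free) == (7, 7)
        assert (est.added_sugars, est.free_sugars) == (4.0, 6.0)

    def test_reference_step8_scales_from_reference(self):
        ref = single("candy", Category.CONFECTIONERY, 60.0,
                     flags=FoodFlags(sugars_all_added=True))
        cfg = ProcedureConfig(proportional_reference_map={"bar": ("candy", 0.25)})
        est = estimate_one(single("bar", Category.OTHER_SINGLE, 20.0), cfg, extra=[ref])
        assert (est.step_added, est.step_free) == (8, 8)
        assert est.added_sugars == pytest.approx(15.0)

    def test_step10_fallback_is_half_total(self):
        est = estimate_one(single("border", Category.OTHER_SINGLE, 8.0))
        assert (est.step_added, est.step_free) == (10, 10)
        assert est.added_sugars == pytest.approx(4.0)

    def test_no_rule_errors_when_fallback_disabled(self):
        with pytest.raises(ValidationError, match="no added-sugars rule"):
            estimate_one(
                single("border", Category.OTHER_SINGLE, 8.0),
                ProcedureConfig(step10_fallback=False),
            )


class TestBreadRule:
    bread = FoodItem("loaf", "loaf", Kind.SINGLE, Category.BREAD_PLAIN,
                     profile=NutrientProfile(0, 1, 1, 1000))

    def test_below_threshold_discounted(self):
        assert bread_rule(self.bread, 1000.0, 8.0, ProcedureConfig()) is True

    def test_at_threshold_not_discounted(self):
        assert bread_rule(self.bread, 1000.0, 9.0, ProcedureConfig()) is False

    def test_zero_sugars_discounted(self):
        assert bread_rule(self.bread, 1000.0, 0.0, ProcedureConfig()) is True

    def test_non_bread_rejected(self):
        other = FoodItem("x", "x", Kind.SINGLE, Category.OTHER_SINGLE,
                         profile=NutrientProfile(0, 0, 0, 0))
        with pytest.raises(ValidationError, match="non-bread"):
            bread_rule(other, 1000.0, 5.0, ProcedureConfig())


class TestFructoseSubtraction:
    def test_direct_subtraction(self):
        assert fructose_subtraction(NutrientProfile(6, 4, 10, 170, fructose=3)) == 7.0

    def test_zero_fructose_identity(self):
        assert fructose_subtraction(NutrientProfile(3, 2, 5, 85, fructose=0)) == 5.0

    def test_negative_result_clamped(self):
        assert fructose_subtraction(NutrientProfile(2, 0, 2, 34, fructose=1.99999)) \
            == pytest.approx(0.00001)

    def test_missing_fructose_ineligible(self):
        with pytest.raises(ValidationError, match="fructose"):
            fructose_subtraction(NutrientProfile(2, 0, 2, 34))


class TestCompositeRules:
    @pytest.mark.parametrize(
        "steps,expected", [({2, 4}, 4), ({2, 6}, 9), ({1}, 4), ({4}, 4), ({10}, 9)]
    )
    def test_step_rule(self, steps, expected):
        assert composite_step(steps) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            composite_step(set())

    def test_weighted_content(self):
        from sugarsteps import Recipe, RecipeComponent

        syrup = single("syrup", Category.BEVERAGE_SOFT, 50.0,
                       flags=FoodFlags(sugars_all_added=True))
        water = single("water", Category.OTHER_SINGLE, 0.0)
        comp = FoodItem("drink", "drink", Kind.COMPOSITE, Category.COMPOSITE)
        recipe = Recipe("drink", (
            RecipeComponent("drink", "syrup", 50.0),
            RecipeComponent("drink", "water", 50.0),
        ))
        db = FoodDB({"syrup": syrup, "water": water, "drink": comp}, {"drink": recipe})
        estimates = assign_and_estimate(db)
        assert estimates["drink"].added_sugars == pytest.approx(25.0)
        added, free = composite_content(db, "drink", estimates)
        assert added == pytest.approx(25.0)

    def test_composite_of_zero_items_is_zero(self):
        from sugarsteps import Recipe, RecipeComponent

        a = single("a", Category.MEAT_FISH_PLAIN, 0.0)
        comp = FoodItem("c", "c", Kind.COMPOSITE, Category.COMPOSITE)
        recipe = Recipe("c", (RecipeComponent("c", "a", 100.0),))
        db = FoodDB({"a": a, "c": comp}, {"c": recipe})
        est = assign_and_estimate(db)["c"]
        assert (est.step_added, est.added_sugars, est.free_sugars) == (4, 0.0, 0.0)


class TestDistribution:
    def test_all_step_one_is_fully_objective(self):
        from sugarsteps import SugarEstimate

        ests = {f"i{k}": SugarEstimate(f"i{k}", 1, 1, 0.0, 0.0) for k in range(5)}
        df = step_distribution(ests)
        assert df.attrs["objective_added_pct"] == 100
        assert int(df.loc[df["step"] == "total", "count_added"].iloc[0]) == 5

    def test_counts_must_cover_same_total(self):
        with pytest.raises(ValidationError):
            distribution_from_counts([1] * 10, [2] * 10)


def test_determinism_identical_inputs(small_world):
    _, db, _, proc = small_world
    first = assign_and_estimate(db, proc)
    second = assign_and_estimate(db, proc)
    assert first == second


def test_ground_truth_recovery_on_objective_items(small_world):
    _, db, truth, proc = small_world
    estimates = assign_and_estimate(db, proc)
    for row in truth.itertuples():
        est = estimates[row.item_id]
        assert est.step_added == row.step_added, row.item_id
        assert est.step_free == row.step_free, row.item_id
        if row.step_added <= 6:
            assert est.added_sugars == pytest.approx(row.added_g_per100, abs=1e-5)
        if row.step_free <= 6:
            assert est.free_sugars == pytest.approx(row.free_g_per100, abs=1e-5)
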