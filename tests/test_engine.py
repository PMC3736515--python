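"""Model engine: basis conversion, boundary behaviour, category matching,
points scoring and equivalence with a naive brute-force evaluator."""

import numpy as np
import pytest
import yaml

from _modelgen import random_threshold_model
from _oracles import oracle_classify_threshold, oracle_score_points
from conftest import make_composition
from nutriprofile import (
    CategoryRule,
    ConfigError,
    Criterion,
    MissingNutrientError,
    ModelDefinition,
    NutrientComposition,
    assign_category,
    classify,
    evaluate_criterion,
    score_points,
)
from nutriprofile.registry import load_model_file
from nutriprofile.synthetic import ARCHETYPES, GeneratorConfig, generate_dataset
from test_data import make_food


def crit(nutrient="sodium_mg", basis="per_100g", comparator="<=", threshold=300.0, **kw):
    return Criterion(
        nutrient=nutrient, basis=basis, comparator=comparator, threshold=threshold, **kw
    )


class TestEvaluateCriterion:
    def test_boundary_inclusive(self):
        food = make_food("f", nutrients=make_composition(sodium_mg=300.0))
        assert evaluate_criterion(food, crit()).passed

    def test_boundary_complement(self):
        food = make_food("f", nutrients=make_composition(sodium_mg=300.1))
        assert not evaluate_criterion(food, crit()).passed

    @pytest.mark.parametrize(
        "comparator,at_threshold_passes", [("<=", True), ("<", False), (">=", True), (">", False)]
    )
    def test_boundary_exactness_per_comparator(self, comparator, at_threshold_passes):
        food = make_food("f", nutrients=make_composition(sodium_mg=300.0))
        outcome = evaluate_criterion(food, crit(comparator=comparator))
        assert outcome.passed is at_threshold_passes

    def test_per_serving_conversion(self):
        # 5 g/100 g at a 50 g serving is 2.5 g/serving, under a 3 g cap
        food = make_food(
            "f", nutrients=make_composition(total_fat_g=5.0), serving_size_g=50.0
        )
        outcome = evaluate_criterion(
            food, crit("total_fat_g", "per_serving", "<=", 3.0)
        )
        assert outcome.observed == pytest.approx(2.5)
        assert outcome.passed

    def test_pct_energy_conversion(self):
        # 10 g fat = 90 kcal out of 300 kcal -> 30% of energy
        food = make_food(
            "f",
            nutrients=make_composition(
                total_fat_g=10.0, energy_kJ=300 * 4.184, saturated_fat_g=1.0
            ),
        )
        outcome = evaluate_criterion(food, crit("total_fat_g", "pct_energy", "<=", 30.0))
        assert outcome.observed == pytest.approx(30.0)
        assert outcome.passed

    def test_per_100kcal_conversion(self):
        food = make_food(
            "f", nutrients=make_composition(sodium_mg=400.0, energy_kJ=200 * 4.184)
        )
        outcome = evaluate_criterion(food, crit(basis="per_100kcal", threshold=200.0))
        assert outcome.observed == pytest.approx(200.0)

    def test_missing_nutrient_is_hard_error(self):
        food = make_food("nofat", nutrients=NutrientComposition(sodium_mg=10))
        with pytest.raises(MissingNutrientError, match="total_fat_g") as err:
            evaluate_criterion(food, crit("total_fat_g"), model_id="uk")
        assert "nofat" in str(err.value) and "uk" in str(err.value)

    def test_todo_criterion_refuses_evaluation(self):
        todo = Criterion(
            nutrient="sodium_mg", basis="per_100g", comparator="<=",
            threshold=None, todo=True,
        )
        with pytest.raises(ConfigError, match="untranscribed"):
            evaluate_criterion(make_food("f"), todo)


def two_category_model(**options):
    return ModelDefinition(
        model_id="toy",
        name="toy",
        mode="threshold",
        category_rules=(
            CategoryRule(
                category_id="drinks", priority=10, is_drink=True,
                criteria=(crit(threshold=20.0),),
            ),
            CategoryRule(
                category_id="foods", priority=20,
                criteria=(
                    crit(threshold=500.0),
                    crit("total_sugar_g", threshold=10.0),
                ),
            ),
        ),
        options=options,
    )


class TestAssignCategory:
    def test_first_match_in_priority_order(self):
        model = two_category_model()
        drink = make_food("d", is_drink=True)
        assert assign_category(drink, model) == "drinks"
        assert assign_category(make_food("f"), model) == "foods"

    def test_points_mode_distinguishes_food_and_drink(self, uk_model):
        assert assign_category(make_food("d", is_drink=True), uk_model) == "drink"
        assert assign_category(make_food("f"), uk_model) == "food"

    def test_tagged_category_matching(self, registry):
        eu = registry.get("eu_pledge")
        cereal = make_food("c", model_category_tags={"breakfast_cereal"})
        assert assign_category(cereal, eu) == "breakfast_cereals"
        milk = make_food("m", model_category_tags={"milk"})
        assert assign_category(milk, eu) == "milk_and_milk_substitutes"

    def test_catch_all_mandatory(self):
        with pytest.raises(ConfigError, match="catch-all"):
            ModelDefinition(
                model_id="bad", name="bad", mode="threshold",
                category_rules=(
                    CategoryRule(category_id="only", priority=1, is_drink=True),
                ),
            )


class TestUKPointsScoring:
    def test_water_scores_zero_and_drink_approved(self, uk_model):
        water = NutrientComposition(
            energy_kJ=0, saturated_fat_g=0, total_sugar_g=0, sodium_mg=0,
            fruit_veg_nut_pct=0, fibre_g=0, protein_g=0,
        )
        audit, approved = score_points(water, uk_model.points_table, is_drink=True)
        assert audit.score == 0 and approved

    def test_worked_unhealthy_food(self, uk_model):
        # energy 1500 kJ -> 4, sat fat 3 g -> 2 (not >3), sugar 20 g -> 4,
        # sodium 500 mg -> 5: A = 15; fibre 1 g -> 1 C-point; protein barred
        # (A >= 11 and no FVN points): score 14, food not approved.
        nc = NutrientComposition(
            energy_kJ=1500, saturated_fat_g=3, total_sugar_g=20, sodium_mg=500,
            fruit_veg_nut_pct=0, fibre_g=1, protein_g=2,
        )
        audit, approved = score_points(nc, uk_model.points_table, is_drink=False)
        assert audit.a_points == {
            "energy_kJ": 4, "saturated_fat_g": 2, "total_sugar_g": 4, "sodium_mg": 5,
        }
        assert audit.a_total == 15
        assert audit.c_total == 1 and not audit.protein_credited
        assert audit.score == 14 and not approved

    def test_protein_bar_lifted_by_max_fvn(self, uk_model):
        nc = NutrientComposition(
            energy_kJ=1500, saturated_fat_g=3, total_sugar_g=20, sodium_mg=900,
            fruit_veg_nut_pct=85, fibre_g=1, protein_g=9,
        )
        audit, _ = score_points(nc, uk_model.points_table, is_drink=False)
        assert audit.c_points["fruit_veg_nut_pct"] == 5
        assert audit.protein_credited and audit.c_points["protein_g"] == 5

    def test_drink_threshold_stricter_than_food(self, uk_model):
        # Score 2: below the food cut (4) but not the drink cut (1).
        nc = NutrientComposition(
            energy_kJ=700, saturated_fat_g=0, total_sugar_g=0, sodium_mg=0,
            fruit_veg_nut_pct=0, fibre_g=0, protein_g=0,
        )
        _, as_food = score_points(nc, uk_model.points_table, is_drink=False)
        _, as_drink = score_points(nc, uk_model.points_table, is_drink=True)
        assert as_food and not as_drink

    def test_fibre_bands_depend_on_assay(self, uk_model):
        kwargs = dict(
            energy_kJ=0, saturated_fat_g=0, total_sugar_g=0, sodium_mg=0,
            fruit_veg_nut_pct=0, protein_g=0, fibre_g=4.0,
        )
        nsp, _ = score_points(
            NutrientComposition(fibre_method="NSP", **kwargs),
            uk_model.points_table, False,
        )
        aoac, _ = score_points(
            NutrientComposition(fibre_method="AOAC", **kwargs),
            uk_model.points_table, False,
        )
        assert nsp.c_points["fibre_g"] == 5  # 4.0 > 3.5
        assert aoac.c_points["fibre_g"] == 4  # 4.0 > 3.7 but not > 4.7

    def test_missing_component_is_error(self, uk_model):
        with pytest.raises(MissingNutrientError, match="fibre_g"):
            score_points(
                NutrientComposition(
                    energy_kJ=0, saturated_fat_g=0, total_sugar_g=0, sodium_mg=0,
                    fruit_veg_nut_pct=0, protein_g=0,
                ),
                uk_model.points_table, False,
            )


class TestClassify:
    def test_archetype_extremes_under_uk(self, uk_model):
        water = make_food(
            "water", nutrients=ARCHETYPES["bottled_water"]["nutrients"],
            is_drink=True, food_guide_category="fatty_sugary",
            fatty_sugary_subcategory="drink",
        )
        assert classify(water, uk_model).approved
        confectionery = make_food(
            "choc", nutrients=ARCHETYPES["confectionery_bar"]["nutrients"],
            food_guide_category="fatty_sugary", fatty_sugary_subcategory="snack",
        )
        assert not classify(confectionery, uk_model).approved
        peas = make_food("peas", nutrients=ARCHETYPES["garden_peas"]["nutrients"],
                         food_guide_category="fruit_veg")
        assert classify(peas, uk_model).approved

    def test_incomplete_model_refused(self, registry):
        with pytest.raises(ConfigError, match="untranscribed"):
            classify(make_food("f"), registry.get("danish"))

    def test_optional_criterion_only_restricts(self):
        model = ModelDefinition(
            model_id="opt", name="opt", mode="threshold",
            category_rules=(
                CategoryRule(
                    category_id="all", priority=1,
                    criteria=(
                        crit("total_sugar_g", threshold=10.0),
                        crit(
                            "sodium_mg", threshold=100.0,
                            optional=True, option="sodium_considered",
                        ),
                    ),
                ),
            ),
            options={"sodium_considered": False},
        )
        toggled = model.with_options(sodium_considered=True)
        for sugar, sodium in [(5, 50), (5, 500), (20, 50), (20, 500)]:
            food = make_food(
                "f", nutrients=make_composition(total_sugar_g=sugar, sodium_mg=sodium)
            )
            off = classify(food, model).approved
            on = classify(food, toggled).approved
            assert (not off) or on == (sodium <= 100)  # only approved can flip
            assert on <= off  # adding a criterion is monotone restrictive

    def test_audit_lists_each_required_criterion_once(self):
        model = two_category_model()
        result = classify(make_food("f"), model)
        nutrients = [o.criterion.nutrient for o in result.criterion_outcomes]
        assert nutrients == ["sodium_mg", "total_sugar_g"]


class TestMonotonicity:
    NEGATIVE = ("energy_kJ", "saturated_fat_g", "total_sugar_g", "sodium_mg")

    def test_worsening_negative_nutrients_never_lowers_uk_score(self, uk_model, rng):
        table = uk_model.points_table
        for _ in range(400):
            base_vals = dict(
                energy_kJ=float(rng.uniform(0, 3000)),
                saturated_fat_g=float(rng.uniform(0, 12)),
                total_sugar_g=float(rng.uniform(0, 50)),
                sodium_mg=float(rng.uniform(0, 1000)),
                fruit_veg_nut_pct=float(rng.uniform(0, 100)),
                fibre_g=float(rng.uniform(0, 5)),
                protein_g=float(rng.uniform(0, 12)),
            )
            worse = dict(base_vals)
            bumped = self.NEGATIVE[rng.integers(4)]
            worse[bumped] = worse[bumped] * 1.5 + float(rng.uniform(0, 100))
            before, _ = score_points(
                NutrientComposition(**base_vals), table, is_drink=False
            )
            after, _ = score_points(
                NutrientComposition(**worse), table, is_drink=False
            )
            assert after.score >= before.score

    def test_threshold_mode_reject_is_absorbing(self, rng):
        model = two_category_model()
        for _ in range(200):
            nc = make_composition(
                sodium_mg=float(rng.uniform(0, 1000)),
                total_sugar_g=float(rng.uniform(0, 20)),
            )
            food = make_food("f", nutrients=nc)
            before = classify(food, model).approved
            worse = make_food(
                "f",
                nutrients=nc.replace(
                    sodium_mg=nc.sodium_mg + float(rng.uniform(0, 300))
                ),
            )
            after = classify(worse, model).approved
            assert after <= before


class TestEngineOracleEquivalence:
    def test_agrees_with_naive_evaluator_on_random_models(self, tmp_path, rng):
        dataset = generate_dataset(GeneratorConfig(seed=901, n_foods=120, archetypes=()))
        for index in range(8):
            raw = random_threshold_model(rng, f"rand_{index:02d}")
            path = tmp_path / f"rand_{index:02d}.yaml"
            path.write_text(yaml.safe_dump(raw))
            model = load_model_file(path)
            for food in dataset:
                category, approved = oracle_classify_threshold(food, raw)
                result = classify(food, model)
                assert result.matched_category == category
                assert result.approved == approved

    def test_uk_agrees_with_naive_points_oracle(self, uk_model):
        import importlib.resources

        raw = yaml.safe_load(
            (importlib.resources.files("nutriprofile") / "models" / "uk.yaml")
            .read_text()
        )["points"]
        dataset = generate_dataset(GeneratorConfig(seed=902, n_foods=150))
        for food in dataset:
            score, approved = oracle_score_points(food, raw)
            result = classify(food, uk_model)
            assert result.score.score == score
            assert result.approved == approved
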