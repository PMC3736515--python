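"""Declarative nutrient profile model engine.

A model is either *threshold* mode — ordered food categories, each carrying a
set of nutrient criteria that all have to pass — or *points* mode — the
FSA/Ofcom-style scoring scheme in which "negative" components (energy,
saturated fat, total sugar, sodium) accrue A-points, "positive" components
(fruit/veg/nuts, fibre, protein) accrue C-points, and a food is classified as
less healthy when A − C reaches the fail threshold.

Observed values are compared to thresholds exactly as given: no rounding is
applied before comparison, and boundary values obey the comparator (a food at
exactly 300 passes "<= 300"). Criteria whose thresholds are not yet
transcribed from a model's source documentation carry ``todo=True``; such
models load for introspection but refuse to classify.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .data import KJ_PER_KCAL, NUTRIENT_CONCEPTS, FoodRecord, NutrientComposition
from .errors import ConfigError, DataError, MissingNutrientError

BASES = ("per_100g", "per_100kcal", "per_serving", "pct_energy")

COMPARATORS = {
    "<=": operator.le,
    "<": operator.lt,
    ">=": operator.ge,
    ">": operator.gt,
}

#: Atwater energy factors (kcal per gram) for percentage-of-energy criteria.
ATWATER_KCAL_PER_G = {
    "total_fat_g": 9.0,
    "saturated_fat_g": 9.0,
    "trans_fat_g": 9.0,
    "total_sugar_g": 4.0,
    "added_sugar_g": 4.0,
    "protein_g": 4.0,
    "fibre_g": 2.0,
}

#: Valid criterion targets: composition fields plus the derived count of
#: qualifying micronutrient claims.
CRITERION_NUTRIENTS = tuple(NUTRIENT_CONCEPTS)


@dataclass(frozen=True)
class Criterion:
    """One nutrient threshold within a category.

    ``optional`` criteria are evaluated and required only when the model
    option named by ``option`` is switched on (e.g. the Danish model's
    "further consideration" sodium rule). ``todo`` marks a criterion whose
    numeric threshold has not been transcribed yet.
    """

    nutrient: str
    basis: str
    comparator: str
    threshold: Optional[float]
    unit: str = ""
    optional: bool = False
    option: Optional[str] = None
    todo: bool = False

    def __post_init__(self) -> None:
        if self.nutrient not in CRITERION_NUTRIENTS:
            raise ConfigError(f"unknown criterion nutrient {self.nutrient!r}")
        if self.basis not in BASES:
            raise ConfigError(f"unknown criterion basis {self.basis!r}")
        if self.comparator not in COMPARATORS:
            raise ConfigError(f"unknown comparator {self.comparator!r}")
        if self.todo:
            if self.threshold is not None:
                raise ConfigError("todo criterion must not carry a threshold")
        else:
            if self.threshold is None:
                raise ConfigError(
                    f"criterion on {self.nutrient!r} lacks a threshold and is "
                    "not marked todo"
                )
            if self.threshold < 0:
                raise ConfigError(
                    f"threshold must be >= 0, got {self.threshold!r}"
                )
        if self.optional and self.option is None:
            raise ConfigError(
                f"optional criterion on {self.nutrient!r} needs an option name"
            )


@dataclass(frozen=True)
class CriterionOutcome:
    criterion: Criterion
    observed: float
    passed: bool


def _observed_value(food: FoodRecord, criterion: Criterion, model_id: str = "") -> float:
    """Observed value of a criterion's nutrient, converted to its basis."""
    nutrients = food.nutrients
    if criterion.nutrient == "micronutrient_count":
        per_100g = float(len(nutrients.micronutrient_flags))
    else:
        value = nutrients.resolved(criterion.nutrient)
        if value is None:
            raise MissingNutrientError(
                criterion.nutrient, food_id=food.id, model_id=model_id
            )
        per_100g = float(value)

    if criterion.basis == "per_100g":
        return per_100g
    if criterion.basis == "per_serving":
        if food.serving_size_g is None:
            raise DataError(
                f"food '{food.id}' lacks a serving size required by a "
                f"per-serving criterion on {criterion.nutrient}"
            )
        return per_100g * food.serving_size_g / 100.0

    kcal = nutrients.resolved_energy_kcal
    if kcal is None:
        raise MissingNutrientError("energy_kcal", food_id=food.id, model_id=model_id)
    if criterion.basis == "per_100kcal":
        if kcal == 0:
            raise DataError(
                f"food '{food.id}' has zero energy; per-100kcal basis undefined"
            )
        return per_100g / kcal * 100.0
    # pct_energy
    factor = ATWATER_KCAL_PER_G.get(criterion.nutrient)
    if factor is None:
        raise ConfigError(
            f"pct_energy basis undefined for nutrient {criterion.nutrient!r}"
        )
    if kcal == 0:
        raise DataError(
            f"food '{food.id}' has zero energy; pct-energy basis undefined"
        )
    return per_100g * factor / kcal * 100.0


def evaluate_criterion(
    food: FoodRecord, criterion: Criterion, model_id: str = ""
) -> CriterionOutcome:
    """Apply one criterion to one food. Boundary values obey the comparator."""
    if criterion.todo:
        raise ConfigError(
            f"criterion on {criterion.nutrient!r} has an untranscribed "
            f"threshold (model '{model_id or 'unknown'}')"
        )
    observed = _observed_value(food, criterion, model_id)
    passed = COMPARATORS[criterion.comparator](observed, criterion.threshold)
    return CriterionOutcome(criterion=criterion, observed=observed, passed=bool(passed))


@dataclass(frozen=True)
class CategoryRule:
    """One model category: a tag/drink predicate plus its criteria.

    Rules are evaluated in ascending ``priority`` order and the first match
    wins; a rule with no tag requirement and no drink requirement is a
    catch-all. Every model must end in a catch-all so that each food receives
    exactly one category.
    """

    category_id: str
    priority: int
    criteria: tuple[Criterion, ...] = ()
    tags_any: frozenset[str] = frozenset()
    is_drink: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags_any", frozenset(self.tags_any))
        object.__setattr__(self, "criteria", tuple(self.criteria))

    @property
    def is_catch_all(self) -> bool:
        return not self.tags_any and self.is_drink is None

    def matches(self, food: FoodRecord) -> bool:
        if self.tags_any and not (self.tags_any & food.model_category_tags):
            return False
        if self.is_drink is not None and food.is_drink != self.is_drink:
            return False
        return True


def _points_from_bounds(value: float, bounds: tuple[float, ...]) -> int:
    """Points = number of strict lower bounds exceeded (value > bound)."""
    return sum(1 for b in bounds if value > b)


def _points_from_pairs(value: float, pairs: tuple[tuple[float, int], ...]) -> int:
    points = 0
    for bound, pts in pairs:
        if value > bound:
            points = pts
    return points


@dataclass(frozen=True)
class PointsTable:
    """FSA/Ofcom-style points bands.

    A-component bands are ascending strict lower bounds: a value scores one
    point per bound it strictly exceeds (max 10). Fruit/veg/nuts uses explicit
    (bound, points) pairs because its scale is 1/2/5; fibre has one band table
    per assay method (NSP or AOAC). Protein C-points are only credited when
    A-points are below ``protein_bar_a_points`` or fruit/veg/nuts scores at
    least ``protein_bar_fvn_exempt`` points. A food fails (is "less healthy")
    when score = A − C reaches the fail threshold for its class.
    """

    energy_kJ: tuple[float, ...]
    saturated_fat_g: tuple[float, ...]
    total_sugar_g: tuple[float, ...]
    sodium_mg: tuple[float, ...]
    fruit_veg_nut_pct: tuple[tuple[float, int], ...]
    fibre_g: Mapping[str, tuple[float, ...]]
    protein_g: tuple[float, ...]
    protein_bar_a_points: int = 11
    protein_bar_fvn_exempt: int = 5
    fail_threshold_food: float = 4.0
    fail_threshold_drink: float = 1.0

    A_COMPONENTS = ("energy_kJ", "saturated_fat_g", "total_sugar_g", "sodium_mg")
    C_COMPONENTS = ("fruit_veg_nut_pct", "fibre_g", "protein_g")

    def __post_init__(self) -> None:
        for name in self.A_COMPONENTS + ("protein_g",):
            bounds = getattr(self, name)
            if list(bounds) != sorted(bounds) or len(set(bounds)) != len(bounds):
                raise ConfigError(f"{name} bounds must be strictly increasing")
        for name in self.A_COMPONENTS:
            if len(getattr(self, name)) > 10:
                raise ConfigError(f"{name} may award at most 10 points")
        if len(self.protein_g) > 5:
            raise ConfigError("protein_g may award at most 5 points")
        fvn_bounds = [b for b, _ in self.fruit_veg_nut_pct]
        fvn_points = [p for _, p in self.fruit_veg_nut_pct]
        if fvn_bounds != sorted(fvn_bounds) or fvn_points != sorted(fvn_points):
            raise ConfigError("fruit_veg_nut_pct pairs must be increasing")
        for method, bounds in self.fibre_g.items():
            if list(bounds) != sorted(bounds) or len(bounds) > 5:
                raise ConfigError(f"fibre bounds for {method} invalid")

    @property
    def nutrient_fields(self) -> tuple[str, ...]:
        return self.A_COMPONENTS + self.C_COMPONENTS


@dataclass(frozen=True)
class PointsScore:
    """Full audit of one points-mode scoring."""

    a_points: Mapping[str, int]
    c_points: Mapping[str, int]
    a_total: int
    c_total: int
    score: int
    protein_credited: bool


def score_points(
    nutrients: NutrientComposition,
    table: PointsTable,
    is_drink: bool,
    food_id: str = "",
    model_id: str = "",
) -> tuple[PointsScore, bool]:
    """Score one composition against a points table.

    Returns ``(score_audit, approved)``; approved means the score is strictly
    below the fail threshold for the food/drink class.
    """
    values: dict[str, float] = {}
    for name in table.nutrient_fields:
        value = nutrients.resolved(name)
        if value is None:
            raise MissingNutrientError(name, food_id=food_id, model_id=model_id)
        values[name] = float(value)

    a_points = {
        name: _points_from_bounds(values[name], getattr(table, name))
        for name in table.A_COMPONENTS
    }
    a_total = sum(a_points.values())

    fvn_pts = _points_from_pairs(values["fruit_veg_nut_pct"], table.fruit_veg_nut_pct)
    fibre_bounds = table.fibre_g.get(nutrients.fibre_method)
    if fibre_bounds is None:
        raise ConfigError(
            f"points table has no fibre bands for method {nutrients.fibre_method!r}"
        )
    fibre_pts = _points_from_bounds(values["fibre_g"], fibre_bounds)
    protein_raw = _points_from_bounds(values["protein_g"], table.protein_g)
    protein_credited = (
        a_total < table.protein_bar_a_points or fvn_pts >= table.protein_bar_fvn_exempt
    )
    protein_pts = protein_raw if protein_credited else 0

    c_points = {
        "fruit_veg_nut_pct": fvn_pts,
        "fibre_g": fibre_pts,
        "protein_g": protein_pts,
    }
    c_total = fvn_pts + fibre_pts + protein_pts
    score = a_total - c_total
    threshold = table.fail_threshold_drink if is_drink else table.fail_threshold_food
    approved = score < threshold
    audit = PointsScore(
        a_points=a_points,
        c_points=c_points,
        a_total=a_total,
        c_total=c_total,
        score=score,
        protein_credited=protein_credited,
    )
    return audit, approved


@dataclass(frozen=True)
class ModelDefinition:
    """One nutrient profile model, threshold or points mode."""

    model_id: str
    name: str
    mode: str  # "threshold" or "points"
    category_rules: tuple[CategoryRule, ...] = ()
    points_table: Optional[PointsTable] = None
    options: Mapping[str, bool] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", dict(self.options))
        if self.mode == "threshold":
            if not self.category_rules:
                raise ConfigError(f"model '{self.model_id}' has no categories")
            rules = tuple(sorted(self.category_rules, key=lambda r: r.priority))
            object.__setattr__(self, "category_rules", rules)
            ids = [r.category_id for r in rules]
            if len(set(ids)) != len(ids):
                raise ConfigError(
                    f"model '{self.model_id}' has duplicate category ids"
                )
            if not rules[-1].is_catch_all:
                raise ConfigError(
                    f"model '{self.model_id}' lacks a final catch-all category"
                )
        elif self.mode == "points":
            if self.points_table is None:
                raise ConfigError(
                    f"points-mode model '{self.model_id}' lacks a points table"
                )
        else:
            raise ConfigError(
                f"model '{self.model_id}' mode must be 'threshold' or 'points', "
                f"got {self.mode!r}"
            )

    # -- introspection -----------------------------------------------------

    @property
    def n_categories(self) -> int:
        """Number of food categories (points mode distinguishes food/drink)."""
        if self.mode == "points":
            return 2
        return len(self.category_rules)

    def _criteria(self):
        for rule in self.category_rules:
            yield from rule.criteria

    @property
    def nutrient_set(self) -> frozenset[str]:
        """All composition fields any criterion or points component references."""
        if self.mode == "points":
            return frozenset(self.points_table.nutrient_fields)
        return frozenset(c.nutrient for c in self._criteria())

    @property
    def nutrient_concepts(self) -> frozenset[str]:
        """Nutrient concepts referenced, optional criteria included."""
        return frozenset(NUTRIENT_CONCEPTS[n] for n in self.nutrient_set)

    @property
    def counted_nutrient_concepts(self) -> frozenset[str]:
        """Concepts a model is said to "include": non-optional references only.

        The distinction matters for models whose documentation lists a
        nutrient only as a further consideration.
        """
        if self.mode == "points":
            return self.nutrient_concepts
        return frozenset(
            NUTRIENT_CONCEPTS[c.nutrient] for c in self._criteria() if not c.optional
        )

    @property
    def todo_criteria(self) -> tuple[tuple[str, Criterion], ...]:
        if self.mode == "points":
            return ()
        return tuple(
            (rule.category_id, c)
            for rule in self.category_rules
            for c in rule.criteria
            if c.todo
        )

    @property
    def incomplete(self) -> bool:
        """True when any criterion still lacks a transcribed threshold."""
        return bool(self.todo_criteria)

    def with_options(self, **flags: bool) -> "ModelDefinition":
        merged = {**self.options, **flags}
        return replace(self, options=merged)


@dataclass(frozen=True)
class ClassificationResult:
    """Per food-and-model verdict with a full audit trail."""

    food_id: str
    model_id: str
    approved: bool
    matched_category: str
    criterion_outcomes: tuple[CriterionOutcome, ...] = ()
    score: Optional[PointsScore] = None


def assign_category(food: FoodRecord, model: ModelDefinition) -> str:
    """First matching category in priority order (points mode: food/drink)."""
    if model.mode == "points":
        return "drink" if food.is_drink else "food"
    for rule in model.category_rules:
        if rule.matches(food):
            return rule.category_id
    raise ConfigError(
        f"model '{model.model_id}' matched no category for food '{food.id}' "
        "(missing catch-all)"
    )


def classify(food: FoodRecord, model: ModelDefinition) -> ClassificationResult:
    """Classify one food under one model.

    Threshold mode: approved iff every required criterion of the matched
    category passes (optional criteria count only when their option is on).
    Points mode: approved iff the score is below the class fail threshold.
    """
    if model.incomplete:
        missing = sorted({cat for cat, _ in model.todo_criteria})
        raise ConfigError(
            f"model '{model.model_id}' has untranscribed thresholds in "
            f"categories {missing}; exclude it or complete its definition"
        )
    category = assign_category(food, model)
    if model.mode == "points":
        audit, approved = score_points(
            food.nutrients,
            model.points_table,
            food.is_drink,
            food_id=food.id,
            model_id=model.model_id,
        )
        return ClassificationResult(
            food_id=food.id,
            model_id=model.model_id,
            approved=approved,
            matched_category=category,
            score=audit,
        )

    rule = next(r for r in model.category_rules if r.category_id == category)
    outcomes: list[CriterionOutcome] = []
    approved = True
    for criterion in rule.criteria:
        if criterion.optional and not model.options.get(criterion.option, False):
            continue
        outcome = evaluate_criterion(food, criterion, model_id=model.model_id)
        outcomes.append(outcome)
        approved = approved and outcome.passed
    return ClassificationResult(
        food_id=food.id,
        model_id=model.model_id,
        approved=approved,
        matched_category=category,
        criterion_outcomes=tuple(outcomes),
    )
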