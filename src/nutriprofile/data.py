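"""Domain types for advertised foods, their nutrient composition and commercials.

Quantities are expressed per 100 g of food as sold (drinks per 100 ml, with
millilitres treated as grams, i.e. density 1). Every nutrient field may be
absent (``None``); downstream model evaluation treats a required absent
nutrient as a hard error rather than guessing, so incompleteness has to be
resolved explicitly through supplementation (:mod:`nutriprofile.assembly`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional

from .errors import DataError

#: Conversion factor between the two energy units.
KJ_PER_KCAL = 4.184

#: Numeric nutrient fields of :class:`NutrientComposition`, in canonical order.
NUTRIENT_FIELDS = (
    "energy_kJ",
    "energy_kcal",
    "total_fat_g",
    "saturated_fat_g",
    "trans_fat_g",
    "cholesterol_mg",
    "total_sugar_g",
    "added_sugar_g",
    "sodium_mg",
    "protein_g",
    "fibre_g",
    "fruit_veg_nut_pct",
)

#: Mapping of composition fields (plus the synthetic ``micronutrient_count``
#: criterion target) onto the nutrient concepts used for model introspection.
#: The two energy fields are a single concept.
NUTRIENT_CONCEPTS = {
    "energy_kJ": "energy",
    "energy_kcal": "energy",
    "total_fat_g": "fat",
    "saturated_fat_g": "saturated_fat",
    "trans_fat_g": "trans_fat",
    "cholesterol_mg": "cholesterol",
    "total_sugar_g": "total_sugar",
    "added_sugar_g": "added_sugar",
    "sodium_mg": "sodium",
    "protein_g": "protein",
    "fibre_g": "fibre",
    "fruit_veg_nut_pct": "fruit_veg",
    "micronutrient_count": "vitamins_minerals",
}

FIBRE_METHODS = ("NSP", "AOAC")

COMMERCIAL_KINDS = ("single_item", "brand", "meal")

DATA_SOURCES = ("web_site", "packaging", "generic_table", "mixed", "synthetic")

#: Closed list of food-guide categories (UK "Balance of Good Health" groups,
#: plus composite and miscellaneous for foods spanning or escaping them).
FOOD_GUIDE_CATEGORIES = (
    "bread_cereals_potatoes",
    "fruit_veg",
    "meat_fish_alternatives",
    "milk_dairy",
    "fatty_sugary",
    "composite",
    "miscellaneous",
)

#: Sub-split of the fatty and sugary category used for stratified reporting.
FATTY_SUGARY_SUBCATEGORIES = ("snack", "not_snack", "drink")


@dataclass(frozen=True)
class NutrientComposition:
    """Named nutrient quantities per 100 g, every field optionally absent.

    ``fibre_method`` records the assay convention behind ``fibre_g`` (NSP or
    AOAC); points-based scoring selects its fibre band table from it.
    ``micronutrient_flags`` is a set of qualifying micronutrient claims such
    as ``"vitamin_c"`` (each meaning e.g. at least 10% of the daily value).
    """

    energy_kJ: Optional[float] = None
    energy_kcal: Optional[float] = None
    total_fat_g: Optional[float] = None
    saturated_fat_g: Optional[float] = None
    trans_fat_g: Optional[float] = None
    cholesterol_mg: Optional[float] = None
    total_sugar_g: Optional[float] = None
    added_sugar_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    protein_g: Optional[float] = None
    fibre_g: Optional[float] = None
    fruit_veg_nut_pct: Optional[float] = None
    fibre_method: str = "NSP"
    micronutrient_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value):
                raise DataError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise DataError(f"{name} must be >= 0, got {value!r}")
        if self.fruit_veg_nut_pct is not None and self.fruit_veg_nut_pct > 100:
            raise DataError(
                f"fruit_veg_nut_pct must be <= 100, got {self.fruit_veg_nut_pct!r}"
            )
        if self.fibre_method not in FIBRE_METHODS:
            raise DataError(
                f"fibre_method must be one of {FIBRE_METHODS}, got {self.fibre_method!r}"
            )
        if self.energy_kJ is not None and self.energy_kcal is not None:
            expected = KJ_PER_KCAL * self.energy_kcal
            if expected > 0 and abs(self.energy_kJ - expected) > 0.02 * expected:
                raise DataError(
                    f"energy fields disagree: {self.energy_kJ} kJ vs "
                    f"{self.energy_kcal} kcal (x{KJ_PER_KCAL})"
                )
            if expected == 0 and self.energy_kJ > 0:
                raise DataError("energy_kcal is 0 but energy_kJ is positive")
        object.__setattr__(
            self, "micronutrient_flags", frozenset(self.micronutrient_flags)
        )

    def get(self, nutrient: str) -> Optional[float]:
        """Value of one nutrient field, ``None`` when absent."""
        if nutrient not in NUTRIENT_FIELDS:
            raise KeyError(f"unknown nutrient field {nutrient!r}")
        return getattr(self, nutrient)

    @property
    def present_fields(self) -> tuple[str, ...]:
        return tuple(n for n in NUTRIENT_FIELDS if getattr(self, n) is not None)

    def is_complete_for(self, nutrients: Iterable[str]) -> bool:
        return all(self.resolved(n) is not None for n in nutrients)

    def resolved(self, nutrient: str) -> Optional[float]:
        """Like :meth:`get` but derives one energy unit from the other."""
        if nutrient == "energy_kcal":
            return self.resolved_energy_kcal
        if nutrient == "energy_kJ":
            if self.energy_kJ is None and self.energy_kcal is not None:
                return self.energy_kcal * KJ_PER_KCAL
            return self.energy_kJ
        return self.get(nutrient)

    @property
    def resolved_energy_kcal(self) -> Optional[float]:
        """Energy in kcal, derived from kJ (/4.184) when only kJ is given."""
        if self.energy_kcal is not None:
            return self.energy_kcal
        if self.energy_kJ is not None:
            return self.energy_kJ / KJ_PER_KCAL
        return None

    def replace(self, **changes) -> "NutrientComposition":
        return replace(self, **changes)


@dataclass(frozen=True)
class MealComponent:
    """One item of a multi-item meal (a food or the accompanying drink)."""

    nutrients: NutrientComposition
    serving_size_g: float
    role: str = "food"  # "food" or "drink"

    def __post_init__(self) -> None:
        if not (self.serving_size_g > 0) or not math.isfinite(self.serving_size_g):
            raise DataError(
                f"serving_size_g must be > 0, got {self.serving_size_g!r}"
            )
        if self.role not in ("food", "drink"):
            raise DataError(f"role must be 'food' or 'drink', got {self.role!r}")


@dataclass(frozen=True)
class FoodRecord:
    """One advertised product, brand representative or averaged meal."""

    id: str
    name: str
    commercial_kind: str
    nutrients: NutrientComposition
    food_guide_category: str
    commercial_count: int
    serving_size_g: Optional[float] = None
    is_drink: bool = False
    fatty_sugary_subcategory: Optional[str] = None
    model_category_tags: frozenset[str] = frozenset()
    exclusion_tags: frozenset[str] = frozenset()
    data_source: str = "web_site"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("food id must be non-empty")
        if self.commercial_kind not in COMMERCIAL_KINDS:
            raise DataError(
                f"commercial_kind must be one of {COMMERCIAL_KINDS}, "
                f"got {self.commercial_kind!r} (food '{self.id}')"
            )
        if self.food_guide_category not in FOOD_GUIDE_CATEGORIES:
            raise DataError(
                f"food_guide_category must be one of {FOOD_GUIDE_CATEGORIES}, "
                f"got {self.food_guide_category!r} (food '{self.id}')"
            )
        if self.food_guide_category == "fatty_sugary":
            if self.fatty_sugary_subcategory not in FATTY_SUGARY_SUBCATEGORIES:
                raise DataError(
                    "fatty_sugary foods need a subcategory in "
                    f"{FATTY_SUGARY_SUBCATEGORIES}, got "
                    f"{self.fatty_sugary_subcategory!r} (food '{self.id}')"
                )
        elif self.fatty_sugary_subcategory is not None:
            raise DataError(
                f"fatty_sugary_subcategory set on non-fatty_sugary food '{self.id}'"
            )
        if not isinstance(self.commercial_count, int) or self.commercial_count < 0:
            raise DataError(
                f"commercial_count must be a non-negative integer, got "
                f"{self.commercial_count!r} (food '{self.id}')"
            )
        if self.serving_size_g is not None and not (self.serving_size_g > 0):
            raise DataError(
                f"serving_size_g must be > 0, got {self.serving_size_g!r} "
                f"(food '{self.id}')"
            )
        if self.data_source not in DATA_SOURCES:
            raise DataError(
                f"data_source must be one of {DATA_SOURCES}, got "
                f"{self.data_source!r} (food '{self.id}')"
            )
        object.__setattr__(self, "model_category_tags", frozenset(self.model_category_tags))
        object.__setattr__(self, "exclusion_tags", frozenset(self.exclusion_tags))

    @property
    def reporting_category(self) -> str:
        """Food-guide category with the fatty/sugary sub-split applied."""
        if self.food_guide_category == "fatty_sugary":
            return f"fatty_sugary/{self.fatty_sugary_subcategory}"
        return self.food_guide_category

    def replace(self, **changes) -> "FoodRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class CommercialDataset:
    """A set of advertised foods with their broadcast frequencies."""

    foods: tuple[FoodRecord, ...]
    total_commercials: int
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "foods", tuple(self.foods))
        ids = [f.id for f in self.foods]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate food ids: {dupes}")
        total = sum(f.commercial_count for f in self.foods)
        if total != self.total_commercials:
            raise DataError(
                f"total_commercials {self.total_commercials} != sum of "
                f"per-food counts {total}"
            )

    @classmethod
    def from_foods(
        cls, foods: Iterable[FoodRecord], provenance: str = ""
    ) -> "CommercialDataset":
        foods = tuple(foods)
        return cls(
            foods=foods,
            total_commercials=sum(f.commercial_count for f in foods),
            provenance=provenance,
        )

    @property
    def n_foods(self) -> int:
        return len(self.foods)

    def __iter__(self):
        return iter(self.foods)

    def __len__(self) -> int:
        return len(self.foods)
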