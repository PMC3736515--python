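"""Dataset assembly: exclusions, meal averaging, brand representatives,
nutrient supplementation and the branded-vs-generic validity check.

These operations turn a raw table of advertised products into an analysable
:class:`~nutriprofile.data.CommercialDataset`. Exclusion classes are carried
as explicit input tags rather than inferred from names: judgements such as
"retailer offering a broad product range" are not machine-decidable, and tags
keep the rules mechanical and auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .data import (
    NUTRIENT_FIELDS,
    CommercialDataset,
    FoodRecord,
    MealComponent,
    NutrientComposition,
)
from .errors import DataError

#: Recognised exclusion tags, grouped into the four exclusion classes.
EXCLUSION_TAGS = {
    "alcoholic_drink": "alcohol, tea/coffee or chewing gum",
    "tea_coffee": "alcohol, tea/coffee or chewing gum",
    "chewing_gum": "alcohol, tea/coffee or chewing gum",
    "broad_range_retailer": "retailer offering a broad product range",
    "baby_toddler_food": "food for babies or toddlers",
    "weight_loss_gain_shake": "weight-loss or weight-gain shake",
}


def apply_exclusions(
    raw_foods: Iterable[FoodRecord], provenance: str = "post-exclusion"
) -> CommercialDataset:
    """Drop records carrying any exclusion tag; keep the rest unchanged.

    Raises :class:`DataError` for a tag outside :data:`EXCLUSION_TAGS`,
    naming the tag — a typo must not silently retain an excludable record.
    """
    kept: list[FoodRecord] = []
    for food in raw_foods:
        unknown = food.exclusion_tags - set(EXCLUSION_TAGS)
        if unknown:
            raise DataError(
                f"unknown exclusion tag(s) {sorted(unknown)} on food '{food.id}'"
            )
        if not food.exclusion_tags:
            kept.append(food)
    return CommercialDataset.from_foods(kept, provenance=provenance)


def compose_meal(
    components: Sequence[MealComponent],
    fill: Optional[Mapping[str, float]] = None,
) -> tuple[NutrientComposition, float]:
    """Serving-mass-weighted average composition of a multi-item meal.

    Each per-100 g nutrient of the result is sum(value_i * mass_i) / sum(mass_i)
    over all components, drinks included (drink millilitres are treated as
    grams). Returns ``(composition, combined_serving_size_g)``.

    A nutrient present in some components and absent in others is an error
    naming the nutrient, unless ``fill`` supplies a per-100 g value to use for
    the components missing it. Micronutrient flags are unioned: the meal
    contains the micronutrients of its parts.
    """
    components = list(components)
    if not components:
        raise DataError("compose_meal requires at least one component")
    total_mass = sum(c.serving_size_g for c in components)
    if total_mass <= 0:
        raise DataError("total meal mass must be > 0")

    values: dict[str, float] = {}
    for nutrient in NUTRIENT_FIELDS:
        present = [c.nutrients.get(nutrient) for c in components]
        if all(v is None for v in present):
            continue
        if any(v is None for v in present):
            if fill is None or nutrient not in fill:
                raise DataError(
                    f"nutrient '{nutrient}' present in some meal components "
                    "but not all, and no fill value supplied"
                )
            present = [fill[nutrient] if v is None else v for v in present]
        weighted = sum(
            v * c.serving_size_g for v, c in zip(present, components)
        )
        values[nutrient] = weighted / total_mass

    fibre_methods = {
        c.nutrients.fibre_method
        for c in components
        if c.nutrients.fibre_g is not None
    }
    if len(fibre_methods) > 1:
        raise DataError(
            f"meal components mix fibre assay methods {sorted(fibre_methods)}"
        )
    flags = frozenset().union(*(c.nutrients.micronutrient_flags for c in components))
    composition = NutrientComposition(
        fibre_method=next(iter(fibre_methods), "NSP"),
        micronutrient_flags=flags,
        **values,
    )
    return composition, total_mass


def select_brand_representative(
    products: Sequence[FoodRecord], seed: int
) -> FoodRecord:
    """Uniform random choice of one product to represent a brand range.

    Reproducible under the same seed; the selection is recorded in the
    returned record's provenance.
    """
    if not products:
        raise DataError("cannot select a representative from an empty range")
    rng = np.random.default_rng(seed)
    index = int(rng.integers(len(products)))
    chosen = products[index]
    note = (
        f"brand representative: product {index + 1} of {len(products)} "
        f"selected uniformly at random (seed={seed})"
    )
    return chosen.replace(
        provenance=(chosen.provenance + "; " if chosen.provenance else "") + note
    )


def supplement_nutrients(
    branded: NutrientComposition,
    generic: NutrientComposition,
    required: Iterable[str] = (),
) -> tuple[NutrientComposition, tuple[str, ...]]:
    """Fill nutrients absent from branded data with generic-table values.

    Branded values always take precedence. Returns the merged composition and
    the names of the fields that were filled. Any nutrient in ``required``
    still absent after merging raises an error naming it. Idempotent: applying
    the same generic table twice fills nothing the second time.
    """
    filled: list[str] = []
    values: dict[str, float] = {}
    for nutrient in NUTRIENT_FIELDS:
        b = branded.get(nutrient)
        if b is not None:
            values[nutrient] = b
            continue
        g = generic.get(nutrient)
        if g is not None:
            values[nutrient] = g
            filled.append(nutrient)
    for nutrient in required:
        if nutrient not in values:
            raise DataError(
                f"nutrient '{nutrient}' absent from both branded and generic data"
            )
    fibre_method = branded.fibre_method
    if "fibre_g" in filled:
        fibre_method = generic.fibre_method
    flags = branded.micronutrient_flags or generic.micronutrient_flags
    merged = NutrientComposition(
        fibre_method=fibre_method, micronutrient_flags=flags, **values
    )
    return merged, tuple(filled)


def supplement_record(
    food: FoodRecord,
    generic: NutrientComposition,
    required: Iterable[str] = (),
) -> FoodRecord:
    """Record-level supplementation; flips data_source to "mixed" on any fill."""
    merged, filled = supplement_nutrients(food.nutrients, generic, required)
    if not filled:
        return food
    note = f"supplemented from generic table: {', '.join(filled)}"
    source = "mixed" if food.data_source != "generic_table" else "generic_table"
    return food.replace(
        nutrients=merged,
        data_source=source,
        provenance=(food.provenance + "; " if food.provenance else "") + note,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson validity check between branded and generic nutrient values.

    ``slope`` is the least-squares regression slope of generic on branded,
    the over/under-estimation check: slope > 1 means the generic table tends
    to overestimate.
    """

    nutrient: str
    n: int
    r: float
    slope: float
    intercept: float
    defined: bool


def validity_correlation(
    paired: Sequence[tuple[float, float]], nutrient: str = ""
) -> CorrelationResult:
    """Pearson r (and regression slope) between paired branded/generic values.

    Requires at least three finite pairs. Zero variance in either series makes
    the correlation undefined; it is reported as such (``defined=False``,
    NaN statistics) rather than raised, since an all-constant nutrient is a
    legitimate data condition.
    """
    if len(paired) < 3:
        raise DataError("validity correlation needs at least 3 pairs")
    x = np.asarray([p[0] for p in paired], dtype=float)
    y = np.asarray([p[1] for p in paired], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("validity correlation requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            nutrient=nutrient,
            n=len(paired),
            r=math.nan,
            slope=math.nan,
            intercept=math.nan,
            defined=False,
        )
    fit = stats.linregress(x, y)
    return CorrelationResult(
        nutrient=nutrient,
        n=len(paired),
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        defined=True,
    )
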