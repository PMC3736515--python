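"""Synthetic advertised-food datasets.

The real dataset behind the eight-model comparison (336 foods, 11 763
commercials, collected from UK children's television in 2008) is not
publicly deposited, so this module generates datasets with the same
statistical shell: the food-guide category mix, a heavy-tailed broadcast
count distribution rescaled to an exact total, and per-category nutrient
marginals drawn from truncated log-normals whose parameters (shipped in
``data/nutrient_distributions.yaml``) span the pass/fail boundaries of the
scoring bands. A handful of fixed archetype foods (bottled water, garden
peas, porridge oats, lettuce, a confectionery bar) can be injected verbatim
to pin down the extremes every model should agree on.

No attempt is made to mimic real brands or the true joint nutrient
distribution; see the methods note for what that does and does not allow
tests to claim.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .data import (
    CommercialDataset,
    FoodRecord,
    NutrientComposition,
)
from .engine import classify
from .errors import ConfigError, DataError
from .registry import ModelRegistry

DEFAULT_N_FOODS = 336
DEFAULT_TOTAL_COMMERCIALS = 11763

#: Default food counts per category (the study-condition mix).
DEFAULT_CATEGORY_FOOD_COUNTS = {
    "bread_cereals_potatoes": 51,
    "composite": 80,
    "fatty_sugary": 125,
    "fruit_veg": 10,
    "meat_fish_alternatives": 15,
    "milk_dairy": 41,
    "miscellaneous": 14,
}

DEFAULT_FATTY_SUGARY_SPLIT = {"snack": 91, "not_snack": 14, "drink": 20}

#: Default commercial weight per category, used to set per-category mean
#: broadcast counts (milk/dairy products are advertised far more often per
#: food than fruit and vegetables).
DEFAULT_CATEGORY_COMMERCIALS = {
    "bread_cereals_potatoes": 2821,
    "composite": 2346,
    "fatty_sugary": 3217,
    "fruit_veg": 234,
    "meat_fish_alternatives": 257,
    "milk_dairy": 2381,
    "miscellaneous": 520,
}

_ZERO = dict(
    energy_kJ=0.0,
    energy_kcal=0.0,
    total_fat_g=0.0,
    saturated_fat_g=0.0,
    trans_fat_g=0.0,
    cholesterol_mg=0.0,
    total_sugar_g=0.0,
    added_sugar_g=0.0,
    sodium_mg=0.0,
    protein_g=0.0,
    fibre_g=0.0,
    fruit_veg_nut_pct=0.0,
)

#: Fixed archetype foods injected verbatim (category, subcategory, is_drink,
#: serving size, tags, full composition).
ARCHETYPES: dict[str, dict] = {
    "bottled_water": dict(
        category="fatty_sugary",
        subcategory="drink",
        is_drink=True,
        serving_size_g=500.0,
        tags=frozenset(),
        nutrients=NutrientComposition(**_ZERO),
    ),
    "garden_peas": dict(
        category="fruit_veg",
        subcategory=None,
        is_drink=False,
        serving_size_g=80.0,
        tags=frozenset({"vegetable"}),
        nutrients=NutrientComposition(
            energy_kJ=290.0,
            total_fat_g=0.9,
            saturated_fat_g=0.2,
            trans_fat_g=0.0,
            cholesterol_mg=0.0,
            total_sugar_g=2.3,
            added_sugar_g=0.0,
            sodium_mg=5.0,
            protein_g=5.5,
            fibre_g=4.2,
            fruit_veg_nut_pct=100.0,
        ),
    ),
    "porridge_oats": dict(
        category="bread_cereals_potatoes",
        subcategory=None,
        is_drink=False,
        serving_size_g=40.0,
        tags=frozenset({"breakfast_cereal"}),
        nutrients=NutrientComposition(
            energy_kJ=1580.0,
            total_fat_g=8.0,
            saturated_fat_g=1.5,
            trans_fat_g=0.0,
            cholesterol_mg=0.0,
            total_sugar_g=1.1,
            added_sugar_g=0.0,
            sodium_mg=2.0,
            protein_g=11.0,
            fibre_g=7.0,
            fruit_veg_nut_pct=0.0,
        ),
    ),
    "lettuce": dict(
        category="fruit_veg",
        subcategory=None,
        is_drink=False,
        serving_size_g=50.0,
        tags=frozenset({"vegetable"}),
        nutrients=NutrientComposition(
            energy_kJ=60.0,
            total_fat_g=0.3,
            saturated_fat_g=0.1,
            trans_fat_g=0.0,
            cholesterol_mg=0.0,
            total_sugar_g=1.7,
            added_sugar_g=0.0,
            sodium_mg=3.0,
            protein_g=0.9,
            fibre_g=1.2,
            fruit_veg_nut_pct=100.0,
        ),
    ),
    "confectionery_bar": dict(
        category="fatty_sugary",
        subcategory="snack",
        is_drink=False,
        serving_size_g=45.0,
        tags=frozenset({"confectionery"}),
        nutrients=NutrientComposition(
            energy_kJ=2200.0,
            total_fat_g=30.0,
            saturated_fat_g=18.0,
            trans_fat_g=0.2,
            cholesterol_mg=10.0,
            total_sugar_g=60.0,
            added_sugar_g=55.0,
            sodium_mg=150.0,
            protein_g=4.0,
            fibre_g=1.0,
            fruit_veg_nut_pct=0.0,
        ),
    ),
}

_MICRONUTRIENT_POOL = ("vitamin_c", "vitamin_d", "calcium", "iron")


def load_nutrient_params(path: Optional[Path] = None) -> dict:
    """Per-category [median, sigma, max] sampling parameters."""
    if path is None:
        path = Path(
            importlib.resources.files("nutriprofile") / "data" / "nutrient_distributions.yaml"
        )
    params = yaml.safe_load(Path(path).read_text())
    if not isinstance(params, dict) or not params:
        raise ConfigError(f"invalid nutrient distribution file {path}")
    return params


def _normalised(mix: Mapping[str, float], what: str) -> dict[str, float]:
    total = float(sum(mix.values()))
    if total <= 0 or any(v < 0 for v in mix.values()):
        raise ConfigError(f"{what} must be non-negative with positive total")
    return {k: v / total for k, v in mix.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic dataset.

    ``category_mix`` and ``fatty_sugary_split`` are proportions (any positive
    weights; normalised internally); defaults reproduce the study mix of 336
    foods and 11 763 commercials. ``seed`` is mandatory.
    """

    seed: int
    n_foods: int = DEFAULT_N_FOODS
    total_commercials: int = DEFAULT_TOTAL_COMMERCIALS
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FOOD_COUNTS)
    )
    fatty_sugary_split: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FATTY_SUGARY_SPLIT)
    )
    category_commercials: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COMMERCIALS)
    )
    count_sigma: float = 1.2
    archetypes: tuple[str, ...] = tuple(ARCHETYPES)
    nutrient_params_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_foods < 1:
            raise ConfigError("n_foods must be >= 1")
        if self.total_commercials < self.n_foods:
            raise ConfigError(
                "total_commercials must be >= n_foods (each food airs at least once)"
            )
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ConfigError(f"unknown archetypes {sorted(unknown)}")
        _normalised(self.category_mix, "category_mix")
        _normalised(self.fatty_sugary_split, "fatty_sugary_split")


def _draw_lognormal(rng, median: float, sigma: float, maximum: float) -> float:
    if median <= 0 or sigma <= 0:
        return float(min(max(median, 0.0), maximum))
    value = median * float(np.exp(sigma * rng.standard_normal()))
    return float(min(value, maximum))


def _sample_composition(rng, params: Mapping) -> tuple[NutrientComposition, float]:
    """One food's composition plus serving size from category parameters.

    Only energy_kJ is stored for energy (kcal resolves by /4.184), total fat
    is saturated + unsaturated, trans fat is a small fraction of saturated
    fat and added sugar a fraction of total sugar, keeping the composition
    internally consistent by construction.
    """
    def draw(key):
        median, sigma, maximum = params[key]
        return _draw_lognormal(rng, float(median), float(sigma), float(maximum))

    sat = round(draw("saturated_fat_g"), 2)
    unsat = round(draw("unsat_fat_g"), 2)
    sugar = round(draw("total_sugar_g"), 2)
    composition = NutrientComposition(
        energy_kJ=round(draw("energy_kJ"), 1),
        total_fat_g=round(sat + unsat, 2),
        saturated_fat_g=sat,
        trans_fat_g=round(sat * 0.05 * float(rng.random()), 3),
        cholesterol_mg=round(draw("cholesterol_mg"), 1),
        total_sugar_g=sugar,
        added_sugar_g=round(sugar * float(rng.uniform(0.5, 1.0)), 2),
        sodium_mg=round(draw("sodium_mg"), 1),
        protein_g=round(draw("protein_g"), 2),
        fibre_g=round(draw("fibre_g"), 2),
        fruit_veg_nut_pct=round(draw("fruit_veg_nut_pct"), 1),
        micronutrient_flags=frozenset(
            flag for flag in _MICRONUTRIENT_POOL if rng.random() < 0.15
        ),
    )
    serving = max(10.0, round(draw("serving_size_g"), 1))
    return composition, serving


def _category_tags(rng, category: str, subcategory: Optional[str]) -> frozenset[str]:
    if category == "milk_dairy":
        return frozenset({"milk" if rng.random() < 0.6 else "dairy_dessert"})
    if category == "bread_cereals_potatoes":
        return frozenset({"breakfast_cereal" if rng.random() < 0.45 else "bread"})
    if category == "fruit_veg":
        return frozenset({"vegetable"})
    if subcategory == "snack":
        return frozenset({"confectionery" if rng.random() < 0.5 else "savoury_snack"})
    return frozenset()


def _sample_slots(rng, config: GeneratorConfig) -> list[tuple[str, Optional[str]]]:
    """Multinomial category (and fatty/sugary subcategory) assignment."""
    mix = _normalised(config.category_mix, "category_mix")
    categories = sorted(mix)
    counts = rng.multinomial(config.n_foods, [mix[c] for c in categories])
    slots: list[tuple[str, Optional[str]]] = []
    for category, count in zip(categories, counts):
        if category == "fatty_sugary":
            split = _normalised(config.fatty_sugary_split, "fatty_sugary_split")
            subcats = sorted(split)
            sub_counts = rng.multinomial(count, [split[s] for s in subcats])
            for sub, sc in zip(subcats, sub_counts):
                slots.extend([(category, sub)] * int(sc))
        else:
            slots.extend([(category, None)] * int(count))
    return slots


def _commercial_counts(rng, config: GeneratorConfig, slots) -> np.ndarray:
    """Heavy-tailed counts rescaled to exactly the configured total."""
    shares = _normalised(config.category_commercials, "category_commercials")
    mix = _normalised(config.category_mix, "category_mix")
    raw = np.empty(len(slots))
    for i, (category, _) in enumerate(slots):
        share = shares.get(category, mix.get(category, 1.0 / len(mix)))
        foods_share = mix.get(category, 1e-9)
        mean_count = config.total_commercials * share / max(
            foods_share * len(slots), 1.0
        )
        raw[i] = mean_count * np.exp(
            config.count_sigma * rng.standard_normal()
            - 0.5 * config.count_sigma**2
        )
    counts = np.maximum(1, np.rint(raw * config.total_commercials / raw.sum()))
    counts = counts.astype(int)
    # Exact rescale: distribute the residual over the largest counts.
    order = np.argsort(-counts, kind="stable")
    diff = config.total_commercials - int(counts.sum())
    i = 0
    while diff != 0:
        j = order[i % len(order)]
        if diff > 0:
            counts[j] += 1
            diff -= 1
        elif counts[j] > 1:
            counts[j] -= 1
            diff += 1
        i += 1
        if i > 10 * len(order) + abs(diff) + 100000:
            raise DataError("could not rescale commercial counts to target")
    return counts


def _archetype_record(name: str, food_id: str, count: int) -> FoodRecord:
    spec = ARCHETYPES[name]
    return FoodRecord(
        id=food_id,
        name=name.replace("_", " "),
        commercial_kind="single_item",
        nutrients=spec["nutrients"],
        food_guide_category=spec["category"],
        fatty_sugary_subcategory=spec["subcategory"],
        is_drink=spec["is_drink"],
        serving_size_g=spec["serving_size_g"],
        model_category_tags=spec["tags"],
        commercial_count=count,
        data_source="synthetic",
        provenance=f"archetype:{name}",
    )


def generate_dataset(config: GeneratorConfig) -> CommercialDataset:
    """Draw one synthetic dataset under the configured study conditions.

    Deterministic in the seed: identical config implies an identical dataset
    (byte-identical once written to CSV).
    """
    rng = np.random.default_rng(config.seed)
    params = load_nutrient_params(config.nutrient_params_path)
    slots = _sample_slots(rng, config)
    if len(config.archetypes) > len(slots):
        raise ConfigError("n_foods too small for the archetype injection list")

    # Reserve the first slot of each archetype's category (or any slot when
    # the multinomial draw left that category empty).
    records: list[Optional[FoodRecord]] = [None] * len(slots)
    taken: set[int] = set()
    archetype_slots: dict[int, str] = {}
    for name in config.archetypes:
        target = (ARCHETYPES[name]["category"], ARCHETYPES[name]["subcategory"])
        index = next(
            (i for i, s in enumerate(slots) if s == target and i not in taken),
            next(i for i in range(len(slots)) if i not in taken),
        )
        taken.add(index)
        archetype_slots[index] = name

    counts = _commercial_counts(rng, config, slots)
    width = max(4, len(str(len(slots))))
    for i, (category, subcategory) in enumerate(slots):
        food_id = f"food_{i + 1:0{width}d}"
        if i in archetype_slots:
            records[i] = _archetype_record(
                archetype_slots[i], food_id, int(counts[i])
            )
            continue
        key = f"{category}/{subcategory}" if subcategory else category
        if key not in params:
            raise ConfigError(f"no nutrient distribution parameters for '{key}'")
        composition, serving = _sample_composition(rng, params[key])
        records[i] = FoodRecord(
            id=food_id,
            name=f"{key.replace('/', ' ')} product {i + 1}",
            commercial_kind="single_item",
            nutrients=composition,
            food_guide_category=category,
            fatty_sugary_subcategory=subcategory,
            is_drink=subcategory == "drink",
            serving_size_g=serving,
            model_category_tags=_category_tags(rng, category, subcategory),
            commercial_count=int(counts[i]),
            data_source="synthetic",
        )
    return CommercialDataset.from_foods(
        records, provenance=f"synthetic:seed={config.seed}"
    )


#: Proposal distributions for ground-truth steering: compositions that lean
#: towards approval (vegetable-like) or rejection (confectionery-like).
_APPROVE_LEANING = "fruit_veg"
_REJECT_LEANING = "fatty_sugary/snack"


def generate_with_ground_truth(
    config: GeneratorConfig,
    planted_rates: Mapping[str, float],
    registry: Optional[ModelRegistry] = None,
    max_tries: int = 500,
) -> tuple[CommercialDataset, pd.DataFrame]:
    """Dataset whose per-model approval flags are planted by construction.

    For each food an intended flag is drawn per model (Bernoulli at the
    planted rate); nutrient vectors are proposed from approve- or
    reject-leaning distributions and rejection-sampled until the engine's
    classification matches every intended flag, which is recorded as ground
    truth. Archetype injection is disabled: this mode is a calibration
    instrument, not a realistic menu. With several mutually contradictory
    models the constraint set can be unsatisfiable, in which case a
    ``ConfigError`` is raised after ``max_tries`` proposals per food.

    Returns ``(dataset, truth)`` with ``truth`` a boolean DataFrame indexed
    by food id, one column per model.
    """
    if registry is None:
        registry = ModelRegistry.from_dir()
    if not planted_rates:
        raise ConfigError("planted_rates must name at least one model")
    models = {}
    for model_id, rate in planted_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"planted rate for '{model_id}' must be in [0, 1]")
        model = registry.get(model_id)
        if model.incomplete:
            raise ConfigError(
                f"model '{model_id}' is incomplete; cannot plant a rate for it"
            )
        models[model_id] = model

    rng = np.random.default_rng(config.seed)
    params = load_nutrient_params(config.nutrient_params_path)
    slots = _sample_slots(rng, config)
    counts = _commercial_counts(rng, config, slots)
    width = max(4, len(str(len(slots))))

    records: list[FoodRecord] = []
    truth_rows: list[dict] = []
    for i, (category, subcategory) in enumerate(slots):
        food_id = f"food_{i + 1:0{width}d}"
        intended = {
            m: bool(rng.random() < planted_rates[m]) for m in sorted(models)
        }
        lean = (
            _APPROVE_LEANING
            if sum(intended.values()) * 2 >= len(intended)
            else _REJECT_LEANING
        )
        record = None
        for _ in range(max_tries):
            composition, serving = _sample_composition(rng, params[lean])
            candidate = FoodRecord(
                id=food_id,
                name=f"planted {category} product {i + 1}",
                commercial_kind="single_item",
                nutrients=composition,
                food_guide_category=category,
                fatty_sugary_subcategory=subcategory,
                is_drink=subcategory == "drink",
                serving_size_g=serving,
                model_category_tags=_category_tags(rng, category, subcategory),
                commercial_count=int(counts[i]),
                data_source="synthetic",
                provenance="planted",
            )
            verdicts = {
                m: classify(candidate, models[m]).approved for m in sorted(models)
            }
            if verdicts == intended:
                record = candidate
                break
        if record is None:
            raise ConfigError(
                f"could not realise intended classifications {intended} for "
                f"food {food_id} within {max_tries} proposals; the planted "
                "rates may be unsatisfiable for these models"
            )
        records.append(record)
        truth_rows.append({"food_id": food_id, **intended})

    dataset = CommercialDataset.from_foods(
        records, provenance=f"synthetic-ground-truth:seed={config.seed}"
    )
    truth = pd.DataFrame(truth_rows).set_index("food_id")
    return dataset, truth
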