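"""Random threshold-model generation for engine/oracle equivalence tests."""

from __future__ import annotations

import numpy as np

#: Tags the synthetic generator actually assigns, so random category rules
#: genuinely match subsets of generated foods.
TAG_POOL = (
    "breakfast_cereal",
    "bread",
    "milk",
    "dairy_dessert",
    "vegetable",
    "confectionery",
    "savoury_snack",
)

#: (nutrient, plausible threshold range). Ranges straddle the synthetic
#: nutrient distributions so both pass and fail outcomes occur.
_NUTRIENT_RANGES = (
    ("total_sugar_g", (2.0, 60.0)),
    ("added_sugar_g", (1.0, 40.0)),
    ("saturated_fat_g", (0.5, 15.0)),
    ("total_fat_g", (1.0, 30.0)),
    ("trans_fat_g", (0.02, 1.0)),
    ("sodium_mg", (50.0, 900.0)),
    ("energy_kcal", (50.0, 600.0)),
    ("cholesterol_mg", (5.0, 150.0)),
    ("protein_g", (1.0, 15.0)),
    ("fibre_g", (0.5, 6.0)),
    ("fruit_veg_nut_pct", (5.0, 90.0)),
    ("micronutrient_count", (0.0, 3.0)),
)

_PCT_ENERGY_OK = {
    "total_fat_g",
    "saturated_fat_g",
    "trans_fat_g",
    "total_sugar_g",
    "added_sugar_g",
    "protein_g",
    "fibre_g",
}


def _random_criterion(rng: np.random.Generator) -> dict:
    nutrient, (lo, hi) = _NUTRIENT_RANGES[rng.integers(len(_NUTRIENT_RANGES))]
    bases = ["per_100g", "per_serving"]
    if nutrient in _PCT_ENERGY_OK:
        bases.append("pct_energy")
    basis = bases[rng.integers(len(bases))]
    threshold = float(np.round(rng.uniform(lo, hi), 2))
    if basis == "pct_energy":
        threshold = float(np.round(rng.uniform(5, 60), 2))
    if basis == "per_serving":
        threshold = float(np.round(threshold * rng.uniform(0.2, 1.5), 2))
    comparator = ("<=", "<", ">=", ">")[rng.integers(4)]
    return {
        "nutrient": nutrient,
        "basis": basis,
        "comparator": comparator,
        "threshold": threshold,
    }


def random_threshold_model(rng: np.random.Generator, model_id: str) -> dict:
    """A valid random threshold-mode model definition mapping."""
    n_extra = int(rng.integers(0, 4))
    categories = []
    for index in range(n_extra):
        match: dict = {}
        if rng.random() < 0.8:
            k = int(rng.integers(1, 3))
            chosen = rng.choice(len(TAG_POOL), size=k, replace=False)
            match["tags_any"] = [TAG_POOL[i] for i in chosen]
        else:
            match["is_drink"] = bool(rng.random() < 0.5)
        categories.append(
            {
                "category_id": f"cat_{index:02d}",
                "priority": (index + 1) * 10,
                "match": match,
                "criteria": [
                    _random_criterion(rng) for _ in range(int(rng.integers(1, 4)))
                ],
            }
        )
    categories.append(
        {
            "category_id": "catch_all",
            "priority": (n_extra + 1) * 10,
            "criteria": [
                _random_criterion(rng) for _ in range(int(rng.integers(1, 4)))
            ],
        }
    )
    return {
        "model_id": model_id,
        "name": f"random model {model_id}",
        "mode": "threshold",
        "categories": categories,
    }
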