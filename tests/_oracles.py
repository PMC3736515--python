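"""Independent brute-force evaluators used only as test oracles.

These deliberately re-read raw model-definition mappings (as parsed straight
from YAML) and evaluate every rule naively, sharing no code with the engine,
so that engine/oracle agreement is a meaningful check.
"""

from __future__ import annotations

import math

_ATWATER = {
    "total_fat_g": 9.0,
    "saturated_fat_g": 9.0,
    "trans_fat_g": 9.0,
    "total_sugar_g": 4.0,
    "added_sugar_g": 4.0,
    "protein_g": 4.0,
    "fibre_g": 2.0,
}


def _naive_value(food, nutrient):
    if nutrient == "micronutrient_count":
        return float(len(food.nutrients.micronutrient_flags))
    value = getattr(food.nutrients, nutrient)
    if value is None and nutrient == "energy_kcal" and food.nutrients.energy_kJ is not None:
        value = food.nutrients.energy_kJ / 4.184
    if value is None and nutrient == "energy_kJ" and food.nutrients.energy_kcal is not None:
        value = food.nutrients.energy_kcal * 4.184
    assert value is not None, f"oracle: nutrient {nutrient} missing on {food.id}"
    return float(value)


def _naive_observed(food, criterion: dict) -> float:
    value = _naive_value(food, criterion["nutrient"])
    basis = criterion.get("basis", "per_100g")
    if basis == "per_100g":
        return value
    if basis == "per_serving":
        return value * food.serving_size_g / 100.0
    kcal = _naive_value(food, "energy_kcal")
    if basis == "per_100kcal":
        return value / kcal * 100.0
    if basis == "pct_energy":
        return value * _ATWATER[criterion["nutrient"]] / kcal * 100.0
    raise AssertionError(f"oracle: unknown basis {basis}")


def _naive_compare(observed: float, comparator: str, threshold: float) -> bool:
    if comparator == "<=":
        return observed <= threshold
    if comparator == "<":
        return observed < threshold
    if comparator == ">=":
        return observed >= threshold
    if comparator == ">":
        return observed > threshold
    raise AssertionError(f"oracle: unknown comparator {comparator}")


def oracle_classify_threshold(food, model_dict: dict, options=None):
    """Naive first-match category assignment + criterion conjunction."""
    flags = {**(model_dict.get("options") or {}), **(options or {})}
    for category in sorted(model_dict["categories"], key=lambda c: c["priority"]):
        match = category.get("match") or {}
        tags = set(match.get("tags_any") or [])
        if tags and not (tags & set(food.model_category_tags)):
            continue
        if match.get("is_drink") is not None and match["is_drink"] != food.is_drink:
            continue
        approved = True
        for criterion in category.get("criteria") or []:
            if criterion.get("optional") and not flags.get(criterion.get("option")):
                continue
            observed = _naive_observed(food, criterion)
            approved = approved and _naive_compare(
                observed, criterion["comparator"], float(criterion["threshold"])
            )
        return category["category_id"], approved
    raise AssertionError(f"oracle: no category matched food {food.id}")


def oracle_score_points(food, points_dict: dict):
    """Naive FSA/Ofcom-style scoring straight from the raw mapping."""

    def band_points(value, bounds):
        points = 0
        for bound in bounds:
            if value > float(bound):
                points += 1
        return points

    a_total = 0
    for component in ("energy_kJ", "saturated_fat_g", "total_sugar_g", "sodium_mg"):
        a_total += band_points(_naive_value(food, component), points_dict[component])

    fvn_value = _naive_value(food, "fruit_veg_nut_pct")
    fvn_points = 0
    for bound, points in points_dict["fruit_veg_nut_pct"]:
        if fvn_value > float(bound):
            fvn_points = int(points)
    fibre_points = band_points(
        _naive_value(food, "fibre_g"),
        points_dict["fibre_g"][food.nutrients.fibre_method],
    )
    protein_points = band_points(_naive_value(food, "protein_g"), points_dict["protein_g"])
    if a_total >= int(points_dict.get("protein_bar_a_points", 11)) and fvn_points < int(
        points_dict.get("protein_bar_fvn_exempt", 5)
    ):
        protein_points = 0

    score = a_total - (fvn_points + fibre_points + protein_points)
    fail_at = (
        float(points_dict.get("fail_threshold_drink", 1))
        if food.is_drink
        else float(points_dict.get("fail_threshold_food", 4))
    )
    return score, score < fail_at


def oracle_kappa(a, b, weights):
    """Textbook 2x2 contingency arithmetic, scalar loops only."""
    n11 = n10 = n01 = n00 = 0.0
    for ai, bi, wi in zip(a, b, weights):
        if ai and bi:
            n11 += wi
        elif ai:
            n10 += wi
        elif bi:
            n01 += wi
        else:
            n00 += wi
    total = n11 + n10 + n01 + n00
    po = (n11 + n00) / total
    pa = (n11 + n10) / total
    pb = (n11 + n01) / total
    pe = pa * pb + (1 - pa) * (1 - pb)
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1 - pe)
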