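"""Reading and writing the package's tabular formats.

The food table is a plain CSV with one row per food, a mandatory header and
the column names below. Absent nutrients are empty cells; set-valued columns
(tags, micronutrient flags) are semicolon-joined. Readers reject unknown
columns unless ``strict=False``: a silently ignored misspelled column would
silently change classifications.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .data import (
    NUTRIENT_FIELDS,
    CommercialDataset,
    FoodRecord,
    NutrientComposition,
)
from .errors import DataError

_META_COLUMNS = (
    "id",
    "name",
    "commercial_kind",
    "food_guide_category",
    "fatty_sugary_subcategory",
    "is_drink",
    "serving_size_g",
    "commercial_count",
    "data_source",
    "model_category_tags",
    "exclusion_tags",
    "fibre_method",
    "micronutrient_flags",
    "provenance",
)

#: Full documented column set of the food table.
FOOD_TABLE_COLUMNS = _META_COLUMNS + NUTRIENT_FIELDS

_REQUIRED_COLUMNS = (
    "id",
    "name",
    "commercial_kind",
    "food_guide_category",
    "is_drink",
    "commercial_count",
)


def _split_set(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(part for part in str(cell).split(";") if part)


def _join_set(values: frozenset[str]) -> str:
    return ";".join(sorted(values))


def _opt_float(cell) -> Optional[float]:
    if cell is None or cell == "" or pd.isna(cell):
        return None
    return float(cell)


def _parse_bool(cell, column: str, row_id: str) -> bool:
    text = str(cell).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise DataError(f"column '{column}' of food '{row_id}': bad boolean {cell!r}")


def read_food_table(path: Path, strict: bool = True) -> list[FoodRecord]:
    """Parse a food-table CSV into records.

    With ``strict`` (default) any column outside the documented set is a
    :class:`DataError`; pass ``strict=False`` to ignore extras.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise DataError(f"food table not found: {path}") from None
    unknown = [c for c in frame.columns if c not in FOOD_TABLE_COLUMNS]
    if unknown and strict:
        raise DataError(
            f"unknown column(s) {unknown} in {path}; pass strict=False to ignore"
        )
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"food table {path} lacks required column(s) {missing}")

    records = []
    for _, row in frame.iterrows():
        row_id = row["id"]

        def cell(column, default=""):
            return row[column] if column in frame.columns else default

        nutrients = NutrientComposition(
            fibre_method=cell("fibre_method") or "NSP",
            micronutrient_flags=_split_set(cell("micronutrient_flags")),
            **{n: _opt_float(cell(n)) for n in NUTRIENT_FIELDS},
        )
        try:
            count = int(cell("commercial_count"))
        except ValueError:
            raise DataError(
                f"food '{row_id}': commercial_count must be an integer, got "
                f"{cell('commercial_count')!r}"
            ) from None
        records.append(
            FoodRecord(
                id=row_id,
                name=cell("name"),
                commercial_kind=cell("commercial_kind"),
                nutrients=nutrients,
                food_guide_category=cell("food_guide_category"),
                fatty_sugary_subcategory=cell("fatty_sugary_subcategory") or None,
                is_drink=_parse_bool(cell("is_drink"), "is_drink", row_id),
                serving_size_g=_opt_float(cell("serving_size_g")),
                commercial_count=count,
                data_source=cell("data_source") or "web_site",
                model_category_tags=_split_set(cell("model_category_tags")),
                exclusion_tags=_split_set(cell("exclusion_tags")),
                provenance=cell("provenance"),
            )
        )
    return records


def write_food_table(foods: Iterable[FoodRecord], path: Path) -> None:
    """Write records to the documented CSV layout (deterministic output)."""
    rows = []
    for food in foods:
        row = {
            "id": food.id,
            "name": food.name,
            "commercial_kind": food.commercial_kind,
            "food_guide_category": food.food_guide_category,
            "fatty_sugary_subcategory": food.fatty_sugary_subcategory or "",
            "is_drink": str(food.is_drink).lower(),
            "serving_size_g": "" if food.serving_size_g is None else repr(food.serving_size_g),
            "commercial_count": food.commercial_count,
            "data_source": food.data_source,
            "model_category_tags": _join_set(food.model_category_tags),
            "exclusion_tags": _join_set(food.exclusion_tags),
            "fibre_method": food.nutrients.fibre_method,
            "micronutrient_flags": _join_set(food.nutrients.micronutrient_flags),
            "provenance": food.provenance,
        }
        for nutrient in NUTRIENT_FIELDS:
            value = food.nutrients.get(nutrient)
            row[nutrient] = "" if value is None else repr(value)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(FOOD_TABLE_COLUMNS))
    frame.to_csv(path, index=False)


def read_dataset(path: Path, strict: bool = True, provenance: str = "") -> CommercialDataset:
    """Food table as a dataset with recomputed commercial total."""
    return CommercialDataset.from_foods(
        read_food_table(path, strict=strict), provenance=provenance or str(path)
    )


def read_generic_table(path: Path, strict: bool = True) -> dict[str, NutrientComposition]:
    """Generic food composition table keyed by generic-food name."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise DataError(f"generic table not found: {path}") from None
    allowed = ("name", "fibre_method", "micronutrient_flags") + NUTRIENT_FIELDS
    unknown = [c for c in frame.columns if c not in allowed]
    if unknown and strict:
        raise DataError(
            f"unknown column(s) {unknown} in {path}; pass strict=False to ignore"
        )
    if "name" not in frame.columns:
        raise DataError(f"generic table {path} lacks the 'name' column")
    table = {}
    for _, row in frame.iterrows():
        name = row["name"]
        if name in table:
            raise DataError(f"duplicate generic food '{name}' in {path}")
        table[name] = NutrientComposition(
            fibre_method=(row.get("fibre_method") or "NSP")
            if "fibre_method" in frame.columns
            else "NSP",
            micronutrient_flags=_split_set(
                row["micronutrient_flags"]
                if "micronutrient_flags" in frame.columns
                else ""
            ),
            **{
                n: _opt_float(row[n]) if n in frame.columns else None
                for n in NUTRIENT_FIELDS
            },
        )
    return table


def load_default_serving_sizes() -> dict[str, float]:
    """Reporting-category serving-size fallbacks shipped with the package."""
    path = Path(
        importlib.resources.files("nutriprofile") / "data" / "serving_size_defaults.csv"
    )
    frame = pd.read_csv(path)
    return dict(zip(frame["category"], frame["serving_size_g"].astype(float)))
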