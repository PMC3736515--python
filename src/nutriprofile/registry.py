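"""Loading and introspection of the shipped model definitions.

Model definitions are YAML files, one per model, under ``models/`` inside the
package (or any directory handed to :meth:`ModelRegistry.from_dir`). Schema
violations are fatal and the error message names the offending file and key.

Several shipped definitions are *structural*: their category layout and
nutrient sets are in place but some numeric thresholds are still marked
``todo`` pending transcription from the model's source documentation. The
registry loads them for introspection; classification refuses them until the
thresholds are filled in.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterator, Optional

import yaml

from .engine import CategoryRule, Criterion, ModelDefinition, PointsTable
from .errors import ConfigError

#: The eight model identifiers the registry recognises.
MODEL_IDS = (
    "brazilian",
    "danish",
    "disney",
    "pepsico",
    "uk",
    "us_cspi",
    "us_interagency",
    "eu_pledge",
)


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key '{key}'")
    return mapping[key]


def _parse_criterion(raw: dict, context: str) -> Criterion:
    if not isinstance(raw, dict):
        raise ConfigError(f"{context}: criterion must be a mapping, got {raw!r}")
    todo = bool(raw.get("todo", False))
    threshold = raw.get("threshold")
    if isinstance(threshold, str):
        if threshold.upper() == "TODO":
            todo, threshold = True, None
        else:
            raise ConfigError(
                f"{context}: threshold must be numeric or TODO, got {threshold!r}"
            )
    try:
        return Criterion(
            nutrient=_require(raw, "nutrient", context),
            basis=raw.get("basis", "per_100g"),
            comparator=_require(raw, "comparator", context),
            threshold=None if todo else float(threshold),
            unit=raw.get("unit", ""),
            optional=bool(raw.get("optional", False)),
            option=raw.get("option"),
            todo=todo,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc
    except ConfigError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _parse_category(raw: dict, context: str) -> CategoryRule:
    category_id = _require(raw, "category_id", context)
    ctx = f"{context}, category '{category_id}'"
    match = raw.get("match", {}) or {}
    criteria = tuple(
        _parse_criterion(c, ctx) for c in raw.get("criteria", []) or []
    )
    return CategoryRule(
        category_id=category_id,
        priority=int(_require(raw, "priority", ctx)),
        criteria=criteria,
        tags_any=frozenset(match.get("tags_any", []) or []),
        is_drink=match.get("is_drink"),
    )


def _parse_points(raw: dict, context: str) -> PointsTable:
    def bounds(key):
        return tuple(float(v) for v in _require(raw, key, context))

    fvn = tuple(
        (float(b), int(p)) for b, p in _require(raw, "fruit_veg_nut_pct", context)
    )
    fibre = {
        method: tuple(float(v) for v in b)
        for method, b in _require(raw, "fibre_g", context).items()
    }
    return PointsTable(
        energy_kJ=bounds("energy_kJ"),
        saturated_fat_g=bounds("saturated_fat_g"),
        total_sugar_g=bounds("total_sugar_g"),
        sodium_mg=bounds("sodium_mg"),
        fruit_veg_nut_pct=fvn,
        fibre_g=fibre,
        protein_g=bounds("protein_g"),
        protein_bar_a_points=int(raw.get("protein_bar_a_points", 11)),
        protein_bar_fvn_exempt=int(raw.get("protein_bar_fvn_exempt", 5)),
        fail_threshold_food=float(raw.get("fail_threshold_food", 4)),
        fail_threshold_drink=float(raw.get("fail_threshold_drink", 1)),
    )


def load_model_file(path: Path) -> ModelDefinition:
    """Parse one YAML model definition; errors name the file."""
    context = str(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{context}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{context}: model file must contain a mapping")
    model_id = _require(raw, "model_id", context)
    mode = _require(raw, "mode", context)
    if mode == "points":
        table = _parse_points(_require(raw, "points", context), context)
        rules: tuple[CategoryRule, ...] = ()
    elif mode == "threshold":
        table = None
        rules = tuple(
            _parse_category(c, context)
            for c in _require(raw, "categories", context)
        )
    else:
        raise ConfigError(f"{context}: unknown mode {mode!r}")
    options = {str(k): bool(v) for k, v in (raw.get("options") or {}).items()}
    try:
        return ModelDefinition(
            model_id=model_id,
            name=raw.get("name", model_id),
            mode=mode,
            category_rules=rules,
            points_table=table,
            options=options,
            notes=raw.get("notes", ""),
        )
    except ConfigError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def packaged_models_dir() -> Path:
    return Path(importlib.resources.files("nutriprofile") / "models")


class ModelRegistry:
    """All loaded models, keyed by model_id."""

    def __init__(self, models: dict[str, ModelDefinition]):
        self._models = dict(models)

    @classmethod
    def from_dir(cls, path: Optional[Path] = None) -> "ModelRegistry":
        """Load every ``*.yaml`` under ``path`` (default: packaged models)."""
        directory = Path(path) if path is not None else packaged_models_dir()
        files = sorted(directory.glob("*.yaml"))
        if not files:
            raise ConfigError(f"no model files (*.yaml) found in {directory}")
        models: dict[str, ModelDefinition] = {}
        for file in files:
            model = load_model_file(file)
            if model.model_id in models:
                raise ConfigError(
                    f"duplicate model_id '{model.model_id}' in {file}"
                )
            models[model.model_id] = model
        return cls(models)

    def get(self, model_id: str) -> ModelDefinition:
        try:
            return self._models[model_id]
        except KeyError:
            raise ConfigError(
                f"unknown model '{model_id}'; registered: {sorted(self._models)}"
            ) from None

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._models))

    @property
    def complete_model_ids(self) -> tuple[str, ...]:
        return tuple(m for m in self.model_ids if not self._models[m].incomplete)

    @property
    def incomplete_model_ids(self) -> tuple[str, ...]:
        return tuple(m for m in self.model_ids if self._models[m].incomplete)

    def models_using(self, concept: str, include_optional: bool = False) -> tuple[str, ...]:
        """Model ids whose criteria reference a nutrient concept.

        With ``include_optional=False`` a model counts only when a
        non-optional criterion (or points component) uses the concept.
        """
        hits = []
        for model_id in self.model_ids:
            model = self._models[model_id]
            concepts = (
                model.nutrient_concepts
                if include_optional
                else model.counted_nutrient_concepts
            )
            if concept in concepts:
                hits.append(model_id)
        return tuple(hits)

    def subset(self, model_ids) -> "ModelRegistry":
        return ModelRegistry({m: self.get(m) for m in model_ids})

    def __iter__(self) -> Iterator[ModelDefinition]:
        return iter(self._models[m] for m in self.model_ids)

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._models
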