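"""End-to-end orchestration: assembly, classification, agreement reports.

A run takes a food table (or a synthetic generator configuration), classifies
every food under every fully specified model, and writes four CSV reports:
per-model approval summaries with CIs, the pairwise kappa matrix with
interpretation stars, the per-category commercial approval breakdown, and a
per-food audit with every model's flag and the approving-model count.

Outputs are deterministic: identical configuration and inputs reproduce
byte-identical files (no timestamps; the seed and configuration are echoed
into ``provenance.json`` instead).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .assembly import apply_exclusions, supplement_record
from .data import CommercialDataset
from .engine import ClassificationResult, classify
from .errors import ConfigError
from .io import read_food_table, read_generic_table, write_food_table
from .registry import ModelRegistry
from .stats import (
    AgreementMatrix,
    ApprovalSummary,
    ApprovingModelCounts,
    CategoryBreakdown,
    agreement_matrix,
    approval_summary,
    approving_model_count,
    category_breakdown,
)
from .synthetic import GeneratorConfig, generate_dataset


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation.

    Exactly one of ``input_csv`` or ``generator`` supplies the dataset.
    Models with untranscribed thresholds must be excluded explicitly, either
    by name in ``exclude_models`` or wholesale with ``exclude_incomplete``.
    """

    out_dir: Path
    seed: int
    input_csv: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    models_dir: Optional[Path] = None
    exclude_models: tuple[str, ...] = ()
    exclude_incomplete: bool = False
    danish_sodium: bool = False
    generic_table: Optional[Path] = None
    strict_columns: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of input_csv or generator must be provided"
            )


@dataclass
class PipelineResult:
    dataset: CommercialDataset
    flags_by_model: Mapping[str, Mapping[str, bool]]
    results: Mapping[str, Mapping[str, ClassificationResult]]
    summaries: tuple[ApprovalSummary, ...]
    matrix: AgreementMatrix
    breakdown: CategoryBreakdown
    counts: ApprovingModelCounts
    output_paths: Mapping[str, Path]
    log_lines: tuple[str, ...]


def _resolve_models(config: RunConfig) -> ModelRegistry:
    registry = ModelRegistry.from_dir(config.models_dir)
    excluded = set(config.exclude_models)
    unknown = excluded - set(registry.model_ids)
    if unknown:
        raise ConfigError(f"cannot exclude unknown model(s) {sorted(unknown)}")
    if config.exclude_incomplete:
        excluded |= set(registry.incomplete_model_ids)
    kept = [m for m in registry.model_ids if m not in excluded]
    if not kept:
        raise ConfigError("all models excluded; nothing to classify")
    still_incomplete = [
        m for m in kept if registry.get(m).incomplete
    ]
    if still_incomplete:
        raise ConfigError(
            "model(s) with untranscribed thresholds must be excluded "
            f"explicitly: {still_incomplete}"
        )
    return registry.subset(kept)


def _load_dataset(config: RunConfig, log: list[str]) -> CommercialDataset:
    if config.generator is not None:
        log.append(f"simulate: seed={config.generator.seed}")
        dataset = generate_dataset(config.generator)
        log.append(
            f"simulate: {dataset.n_foods} foods, "
            f"{dataset.total_commercials} commercials"
        )
        return dataset
    records = read_food_table(config.input_csv, strict=config.strict_columns)
    excluded = [r for r in records if r.exclusion_tags]
    for record in excluded:
        log.append(
            f"exclude: {record.id} tags={sorted(record.exclusion_tags)}"
        )
    dataset = apply_exclusions(records, provenance=str(config.input_csv))
    if config.generic_table is not None:
        generic = read_generic_table(config.generic_table)
        patched = []
        for food in dataset:
            entry = generic.get(food.name)
            if entry is not None:
                updated = supplement_record(food, entry)
                if updated is not food:
                    log.append(f"supplement: {food.id} from generic '{food.name}'")
                food = updated
            patched.append(food)
        dataset = CommercialDataset.from_foods(patched, dataset.provenance)
    log.append(
        f"assemble: {dataset.n_foods} foods retained, "
        f"{dataset.total_commercials} commercials"
    )
    return dataset


def _outcome_audit(result: ClassificationResult) -> str:
    if result.score is not None:
        a, c = result.score.a_total, result.score.c_total
        return f"A={a};C={c};score={result.score.score}"
    parts = [
        f"{o.criterion.nutrient}:{o.criterion.basis}="
        f"{o.observed:.4g}{'P' if o.passed else 'F'}"
        for o in result.criterion_outcomes
    ]
    return "|".join(parts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute assembly, classification and the agreement analysis."""
    log: list[str] = [f"run: seed={config.seed}"]
    registry = _resolve_models(config)
    dataset = _load_dataset(config, log)

    results: dict[str, dict[str, ClassificationResult]] = {}
    flags: dict[str, dict[str, bool]] = {}
    for model in registry:
        if config.danish_sodium and model.model_id == "danish":
            model = model.with_options(danish_sodium_considered=True)
        per_food = {food.id: classify(food, model) for food in dataset}
        results[model.model_id] = per_food
        flags[model.model_id] = {fid: r.approved for fid, r in per_food.items()}
        approved = sum(flags[model.model_id].values())
        log.append(
            f"classify: model={model.model_id} foods={dataset.n_foods} "
            f"approved={approved}"
        )

    summaries = tuple(
        approval_summary(flags[m], dataset, model_id=m) for m in sorted(flags)
    )
    matrix = agreement_matrix(flags, dataset)
    breakdown = category_breakdown(flags, dataset)
    counts = approving_model_count(flags, dataset)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = _write_outputs(
        out, config, dataset, results, flags, summaries, matrix, breakdown, counts
    )
    log.append(f"report: wrote {len(paths)} files")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    paths["log"] = out / "run_log.txt"
    return PipelineResult(
        dataset=dataset,
        flags_by_model=flags,
        results=results,
        summaries=summaries,
        matrix=matrix,
        breakdown=breakdown,
        counts=counts,
        output_paths=paths,
        log_lines=tuple(log),
    )


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": s.model_id,
                "n_foods_approved": s.n_foods_approved,
                "pct_foods_approved": round(s.pct_foods_approved, 2),
                "foods_ci_lo": round(s.foods_ci[0], 2),
                "foods_ci_hi": round(s.foods_ci[1], 2),
                "pct_commercials_approved": round(s.pct_commercials_approved, 2),
                "commercials_ci_lo": round(s.commercials_ci[0], 2),
                "commercials_ci_hi": round(s.commercials_ci[1], 2),
            }
            for s in summaries
        ]
    )


def _write_outputs(
    out, config, dataset, results, flags, summaries, matrix, breakdown, counts
):
    paths: dict[str, Path] = {}

    paths["dataset"] = out / "dataset.csv"
    write_food_table(dataset, paths["dataset"])

    paths["approval_summary"] = out / "approval_summary.csv"
    summaries_frame(summaries).to_csv(paths["approval_summary"], index=False)

    paths["kappa_matrix"] = out / "kappa_matrix.csv"
    matrix.starred().to_csv(paths["kappa_matrix"])
    paths["kappa_values"] = out / "kappa_values.csv"
    matrix.kappa.round(4).to_csv(paths["kappa_values"])

    paths["category_breakdown"] = out / "category_breakdown.csv"
    breakdown.table.round(2).to_csv(paths["category_breakdown"])

    model_ids = sorted(flags)
    rows = []
    for food in dataset:
        row = {
            "food_id": food.id,
            "name": food.name,
            "category": food.reporting_category,
            "commercial_count": food.commercial_count,
        }
        for m in model_ids:
            row[f"approved_{m}"] = flags[m][food.id]
            row[f"audit_{m}"] = _outcome_audit(results[m][food.id])
        row["n_models_approving"] = int(counts.counts.loc[food.id])
        rows.append(row)
    paths["per_food"] = out / "per_food.csv"
    pd.DataFrame(rows).to_csv(paths["per_food"], index=False)

    provenance = {
        "seed": config.seed,
        "models": model_ids,
        "danish_sodium": config.danish_sodium,
        "input": str(config.input_csv) if config.input_csv else None,
        "generator": (
            {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config.generator).items()
            }
            if config.generator
            else None
        ),
        "dataset_provenance": dataset.provenance,
    }
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return paths
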