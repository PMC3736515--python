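# nutriprofile

Nutrient profile models classify foods by nutritional composition — typically
to decide which products may be advertised during television viewed by
children. Several such models exist (developed by regulators, academics,
consumer groups and the food industry), and they disagree substantially about
which foods to permit. `nutriprofile` is a toolkit for quantifying that
disagreement on a common dataset of advertised foods:

- a **declarative model engine** — models are YAML definitions, either
  category-specific threshold criteria (e.g. sodium ≤ 300 mg/100 g for milk)
  or FSA/Ofcom-style points scoring — that classifies each food as
  permitted / not permitted with a full per-criterion audit trail;
- a **dataset-assembly layer** — exclusion rules, brand-representative
  selection, serving-mass-weighted meal averaging, generic-table nutrient
  supplementation, and a Pearson validity check between branded and generic
  nutrient data;
- an **agreement layer** — approval proportions per food and per commercial
  (each food weighted by its broadcast count) with binomial 95% CIs,
  pairwise commercial-weighted Cohen's κ with interpretation bands,
  food-guide category breakdowns, and per-food approving-model counts;
- a **synthetic-data generator** that emulates the statistical shell of an
  advertised-food dataset (category mix, heavy-tailed broadcast counts,
  per-category nutrient marginals), so the whole pipeline is testable
  without proprietary data.

The intended users are public-health researchers and policy analysts
comparing candidate models for advertising regulation.

## The statistics at the core

For one model, with $k$ of $n$ foods approved, the food-level approval is
$p_f = k/n$ and the commercial-level approval is
$p_c = \sum_{i \,\text{approved}} w_i / \sum_i w_i$ with $w_i$ the number of
times food $i$'s commercial aired. Both are reported with the
normal-approximation binomial half-width
$h = 1.96\sqrt{p_f(1-p_f)/n}$ — based on *foods* in both cases, since
repeated broadcasts of the same commercial add no sampling variance.

Pairwise agreement between models $A$ and $B$ is Cohen's
$\kappa = (p_o - p_e)/(1 - p_e)$ on the commercial-weighted 2×2 table, with
$p_o$ the weighted fraction classified identically and $p_e$ the chance
agreement from the marginals; bands: ≤0.20 less than fair, 0.21–0.40 fair,
0.41–0.60 moderate, 0.61–0.80 good, >0.80 very good.

The UK FSA/Ofcom model scores A-points for energy, saturated fat, total
sugar and sodium and C-points for fruit/veg/nuts, fibre and protein
(protein barred when A ≥ 11 unless fruit/veg/nuts scores 5); a food is "less
healthy" when A − C ≥ 4 (foods) or ≥ 1 (drinks). The shipped `models/uk.yaml`
carries the full band tables. The other seven shipped model files are
*structural*: category layout and nutrient sets are in place, but numeric
thresholds not available in our sources are marked `todo`, the registry
flags those models incomplete, and classification refuses them until the
thresholds are transcribed from the primary model documentation.

## Worked example

```python
from nutriprofile import ModelRegistry, NutrientComposition, score_points

table = ModelRegistry.from_dir().get("uk").points_table
food = NutrientComposition(
    energy_kJ=1500, saturated_fat_g=3, total_sugar_g=20, sodium_mg=500,
    fruit_veg_nut_pct=0, fibre_g=1, protein_g=2,
)
audit, approved = score_points(food, table, is_drink=False)
print(audit.a_total, audit.c_total, audit.score, approved)
```

prints

```
15 1 14 False
```

15 A-points (energy 4, saturated fat 2, sugar 4, sodium 5), one C-point for
fibre (protein is barred because A ≥ 11 with no fruit/veg/nuts points), a
final score of 14 — far above the food cut-off of 4 — so the food is
classified "less healthy" and would not be permitted.

An end-to-end synthetic run from the shell:

```
nutriprofile run --seed 7 --out-dir out/ --exclude-incomplete
```

writes `dataset.csv`, `approval_summary.csv` (per-model approval percentages
with CIs), `kappa_matrix.csv` (pairwise κ with band stars),
`category_breakdown.csv` and a `per_food.csv` audit. With only the UK model
complete the κ matrix is the trivial 1×1 identity; drop further completed
model files into a `--models-dir` to widen the comparison.

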