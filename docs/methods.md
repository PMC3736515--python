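# Methods

This note records the modelling and numerical choices behind `nutriprofile`:
what the engine and statistics assume, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Classification engine

A model definition is either **threshold mode** — an ordered list of
category rules, each with a tag/drink predicate and a conjunction of
nutrient criteria — or **points mode** — FSA/Ofcom-style band scoring.

*Category matching* is priority-ordered first-match. Model documentation
rarely states a tie-break when a food fits several categories, so the order
is part of the model definition and a final catch-all rule is mandatory;
a model whose rules can fail to match any food is rejected at load time.

*Criterion bases.* A criterion compares an observed value, converted to one
of four bases, against a threshold:

- `per_100g` — the stored value (drinks per 100 ml, density 1);
- `per_serving` — value × serving size / 100; requires a declared serving
  size at evaluation time;
- `per_100kcal` — value / energy (kcal) × 100;
- `pct_energy` — value × Atwater factor (9 kcal/g fats, 4 kcal/g sugars and
  protein, 2 kcal/g fibre) / energy × 100.

Energy in kcal is derived from kJ (÷ 4.184) when only kJ is stored; when
both are present they must agree within 2%.

*Exactness.* Observed values are compared unrounded, and boundary values
obey the comparator: a food at exactly 300 passes "≤ 300". Rounding before
comparison would silently flip classifications near thresholds, and no
rounding convention is part of any model definition we ship.

*Missing data.* A nutrient required by a criterion but absent from the food
is a hard error naming the food, model and nutrient — never an implicit pass
or fail. Completeness is meant to be established up front via generic-table
supplementation (below).

*Optional criteria.* Some models list a criterion only as a "further
consideration" (the Danish sodium rule is the canonical case, and its
applicability is explicitly unclear in the model's description). Such
criteria carry an option flag, default off; switching the option on can only
flip a verdict from approved to not-approved (adding a conjunct is monotone
restrictive), which the tests verify. Because the rule's placement is
unclear, the shipped Danish definition attaches it per category rather than
globally; the flag governs all instances at once, so the distinction has no
effect on any shipped computation.

*Points scoring.* A-points accrue for energy (kJ), saturated fat, total
sugar and sodium — one point per strict lower bound exceeded, 10 bounds per
component; C-points for fruit/veg/nuts (1/2/5 scale), fibre (5 bounds, with
separate NSP and AOAC band tables selected by the food's declared assay
method) and protein (5 bounds). Protein is credited only when A < 11 or
fruit/veg/nuts scores the full 5 points. Score = A − C; a food is "less
healthy" at score ≥ 4, a drink at ≥ 1. Both cut-offs are configuration with
these published defaults.

*Incomplete models.* Seven of the eight shipped definitions include
criteria whose numeric thresholds were not available in our sources; they
are marked `todo` in the YAML. Inventing thresholds would produce plausible
but wrong classifications, so the registry flags these models incomplete,
they are excluded from default runs, and classification raises until the
thresholds are transcribed from the primary documentation. Their category
counts, nutrient sets and the two documented EU Pledge sodium thresholds
(≤ 300 mg/100 g milk and milk substitutes, ≤ 450 mg/100 g breakfast
cereals) are in place, so registry introspection is meaningful.

## Dataset assembly

- **Exclusions** (alcohol/tea/coffee/chewing gum, broad-range retailers,
  baby/toddler foods, weight-loss/gain shakes) are explicit input tags, not
  inferred from names: several of the judgements are not machine-decidable,
  and tags keep the rule auditable. Unknown tags are fatal.
- **Meal averaging** combines components by serving mass:
  nutrient = Σ(valueᵢ·massᵢ)/Σ(massᵢ), drinks included, millilitres treated
  as grams (density 1; no density convention is part of the procedure this
  mirrors). A nutrient present in some components only is an error unless a
  fill value is supplied. Micronutrient flags are unioned; fibre assay
  methods must agree across components.
- **Brand representatives** are a uniform random choice under a mandatory
  seed, recorded in provenance.
- **Supplementation** fills absent branded nutrients from a generic
  composition table, branded values always winning; any fill flips the
  record's data source to "mixed". The operation is idempotent.
- **Validity** between branded and generic values is the Pearson r plus the
  least-squares slope (the over/under-estimation check), computed on raw
  per-100 g values without transform. Zero variance in either series is
  reported as undefined rather than raised.
- When serving sizes are missing, a per-category lookup
  (`data/serving_size_defaults.csv`) supplies fallbacks.

## Agreement statistics

Approval CIs use the normal-approximation binomial with n = number of
foods, applied to both the food-level and the commercial-weighted point
estimates: repeated broadcasts of one commercial are not independent
observations, so the food-based standard error is the defensible one for
both. z = 1.96; intervals are clipped to [0, 100]. This construction
reproduces the published intervals it is checked against to their printed
precision, apart from two classes of printing artefacts: one half-way
rounding case on the food side (a reconstructed bound of 0.7508 prints as
0.8 where 0.7 was published), and commercial-side bounds whose published
point estimates are themselves rounded to 1 dp (adding up to 0.05 of input
slack). Tests therefore assert food-side bounds within 0.06 and
commercial-side bounds within 0.1 of print.

Cohen's κ is computed on the weighted 2×2 table with each food contributing
its commercial count as a frequency weight; no bias/prevalence correction.
Perfect observed agreement returns κ = 1 exactly; chance agreement of 1
with imperfect observed agreement is undefined and reported as NaN.
Interpretation bands follow the conventional cut points with boundary
values belonging to the band whose printed range names them (0.40 is
"fair", 0.41 "moderate", 0.60 "moderate", 0.61 "good", 0.80 "good").

Reported percentages and κ are rounded (half-up, 1–2 dp) only at output,
never internally.

## Synthetic data

The generator emulates the statistical shell of an advertised-food dataset:

- the food-guide category mix (multinomial over the study proportions —
  default 336 foods: 51 bread/cereals/potatoes, 80 composite, 125
  fatty/sugary split 91 snacks / 14 not-snacks / 20 drinks, 10 fruit/veg,
  15 meat/fish, 41 milk/dairy, 14 miscellaneous);
- heavy-tailed commercial counts: log-normal draws (σ = 1.2) with
  per-category means proportional to the study's per-category commercial
  totals, rounded, floored at 1 and exactly rescaled to the default total
  of 11 763;
- per-category nutrient marginals: truncated log-normals with parameters
  shipped in `data/nutrient_distributions.yaml`, chosen for non-negativity
  and realistic right skew and to straddle each scoring band (cereals
  around the sugar bands, snacks far beyond them, drinks near the
  zero-score neighbourhood). Internal consistency is by construction:
  total fat = saturated + unsaturated draw, trans fat a small fraction of
  saturated, added sugar a fraction of total sugar, kcal derived from kJ;
- fixed archetypes injected verbatim (bottled water, garden peas, porridge
  oats, lettuce, a confectionery bar) pinning the extremes every sensible
  model agrees on.

It does **not** emulate the joint nutrient distribution of real advertised
foods, brand identities, or any correlation between nutrient profile and
broadcast frequency. Passing tests on synthetic data therefore demonstrate
the correctness and calibration of the machinery (engine, CIs, κ,
pipeline), not the real-data approval percentages or κ values of any
particular market, which require the original dataset.

`generate_with_ground_truth` plants per-model approval flags: an intended
flag is drawn per food (Bernoulli at the planted rate), and nutrient
vectors are rejection-sampled from approve-leaning (vegetable-like) or
reject-leaning (confectionery-like) proposals until the engine's verdict
matches the intent, which is recorded as truth. With several mutually
contradictory models the constraint set can be unsatisfiable; the operation
errors after a bounded number of proposals. Its intended use is single-model
calibration (recovery of planted rates, CI coverage).

## Problem sizes and numerical checks

The shipped verification suite uses: 1 000 synthetic foods for
engine-vs-naive-oracle agreement (plus five random threshold models on 200
foods), 1 000 random weighted classifications for κ-vs-contingency
agreement, 10 000 random perturbations for points-score monotonicity,
2 000 replicates at n = 336 for CI coverage, 300 replicates for the κ
independence null, and two full 336-food pipeline runs for byte-level
determinism. These sizes give comfortable binomial/Monte-Carlo margins
(3 σ bounds) for every stochastic assertion.

## Known limitations

- Only the UK model is fully specified; cross-model agreement on the
  shipped registry degenerates to a 1×1 matrix until further thresholds are
  transcribed. The engine, statistics and pipeline are exercised on
  synthetic multi-model classifications instead.
- The commercial-count model is a convenience (log-normal, exact-total
  rescale); real broadcast schedules have structure (campaigns,
  seasonality) it ignores.
- Meal averaging dilutes drinks into food nutrient densities by design;
  regulators assessing multi-product commercials may instead require each
  component to pass individually, which this package does not implement.
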