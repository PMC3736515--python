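# PepsiCo model: criteria over energy, added sugar, fat, saturated fat,
# trans fat, cholesterol, sodium, protein, fibre and micronutrients across
# 7 product categories. Note: the model's published summary counts 9
# included nutrients while marking 10 nutrient columns; this file carries
# the 10 marked concepts pending verification against the primary criteria
# document.
#
# STRUCTURAL DEFINITION: numeric thresholds and category identities pending
# transcription from the model's source documentation; the registry flags
# this model incomplete and excludes it from classification runs.
model_id: pepsico
name: PepsiCo model
mode: threshold
categories:
  - category_id: pending_category_01
    priority: 10
    match: {tags_any: [pepsico_cat_01]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_02
    priority: 20
    match: {tags_any: [pepsico_cat_02]}
    criteria:
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: cholesterol_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_03
    priority: 30
    match: {tags_any: [pepsico_cat_03]}
    criteria:
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: protein_g, basis: per_serving, comparator: ">=", todo: true}
  - category_id: pending_category_04
    priority: 40
    match: {tags_any: [pepsico_cat_04]}
    criteria:
      - {nutrient: fibre_g, basis: per_serving, comparator: ">=", todo: true}
      - {nutrient: micronutrient_count, basis: per_100g, comparator: ">=", todo: true}
  - category_id: pending_category_05
    priority: 50
    match: {tags_any: [pepsico_cat_05]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: drinks
    priority: 60
    match: {is_drink: true}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: other_foods
    priority: 70
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: cholesterol_mg, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: protein_g, basis: per_serving, comparator: ">=", todo: true}
      - {nutrient: fibre_g, basis: per_serving, comparator: ">=", todo: true}
      - {nutrient: micronutrient_count, basis: per_100g, comparator: ">=", todo: true}
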