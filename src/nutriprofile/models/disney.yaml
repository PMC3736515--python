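# Disney model: thresholds on energy, added sugar, total sugar, saturated
# fat, trans fat and sodium over 17 food categories.
#
# STRUCTURAL DEFINITION: numeric thresholds and category identities pending
# transcription from the model's source documentation; the registry flags
# this model incomplete and excludes it from classification runs.
model_id: disney
name: Disney model
mode: threshold
categories:
  - category_id: pending_category_01
    priority: 10
    match: {tags_any: [disney_cat_01]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_02
    priority: 20
    match: {tags_any: [disney_cat_02]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_03
    priority: 30
    match: {tags_any: [disney_cat_03]}
    criteria:
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_04
    priority: 40
    match: {tags_any: [disney_cat_04]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_05
    priority: 50
    match: {tags_any: [disney_cat_05]}
    criteria:
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_06
    priority: 60
    match: {tags_any: [disney_cat_06]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_07
    priority: 70
    match: {tags_any: [disney_cat_07]}
    criteria:
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_08
    priority: 80
    match: {tags_any: [disney_cat_08]}
    criteria:
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_09
    priority: 90
    match: {tags_any: [disney_cat_09]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_10
    priority: 100
    match: {tags_any: [disney_cat_10]}
    criteria:
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_11
    priority: 110
    match: {tags_any: [disney_cat_11]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_12
    priority: 120
    match: {tags_any: [disney_cat_12]}
    criteria:
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_13
    priority: 130
    match: {tags_any: [disney_cat_13]}
    criteria:
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_14
    priority: 140
    match: {tags_any: [disney_cat_14]}
    criteria:
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_15
    priority: 150
    match: {tags_any: [disney_cat_15]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
  - category_id: drinks
    priority: 160
    match: {is_drink: true}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: other_foods
    priority: 170
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
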