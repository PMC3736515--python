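# US CSPI model: criteria on added sugar, fat, trans fat and sodium over
# 6 product categories.
#
# STRUCTURAL DEFINITION: numeric thresholds and category identities pending
# transcription from the model's source documentation; the registry flags
# this model incomplete and excludes it from classification runs.
model_id: us_cspi
name: US CSPI model
mode: threshold
categories:
  - category_id: pending_category_01
    priority: 10
    match: {tags_any: [cspi_cat_01]}
    criteria:
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: pending_category_02
    priority: 20
    match: {tags_any: [cspi_cat_02]}
    criteria:
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_03
    priority: 30
    match: {tags_any: [cspi_cat_03]}
    criteria:
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_04
    priority: 40
    match: {tags_any: [cspi_cat_04]}
    criteria:
      - {nutrient: total_fat_g, basis: pct_energy, comparator: "<=", todo: true}
  - category_id: drinks
    priority: 50
    match: {is_drink: true}
    criteria:
      - {nutrient: added_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: other_foods
    priority: 60
    criteria:
      - {nutrient: added_sugar_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
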