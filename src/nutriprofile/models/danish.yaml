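# Danish model: thresholds on total sugar and fat over 10 food categories.
# Its documentation lists an additional sodium criterion only as a "further
# consideration" without stating when it applies; that criterion is therefore
# optional here, governed by the `danish_sodium_considered` flag (default
# off), and does not count towards the model's included nutrients.
#
# STRUCTURAL DEFINITION: numeric thresholds and category identities pending
# transcription from the model's source documentation; the registry flags
# this model incomplete and excludes it from classification runs.
model_id: danish
name: Danish model
mode: threshold
options:
  danish_sodium_considered: false
categories:
  - category_id: pending_category_01
    priority: 10
    match: {tags_any: [danish_cat_01]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true,
         optional: true, option: danish_sodium_considered}
  - category_id: pending_category_02
    priority: 20
    match: {tags_any: [danish_cat_02]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true,
         optional: true, option: danish_sodium_considered}
  - category_id: pending_category_03
    priority: 30
    match: {tags_any: [danish_cat_03]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_04
    priority: 40
    match: {tags_any: [danish_cat_04]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_05
    priority: 50
    match: {tags_any: [danish_cat_05]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_06
    priority: 60
    match: {tags_any: [danish_cat_06]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_07
    priority: 70
    match: {tags_any: [danish_cat_07]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_08
    priority: 80
    match: {tags_any: [danish_cat_08]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: drinks
    priority: 90
    match: {is_drink: true}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: other_foods
    priority: 100
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true,
         optional: true, option: danish_sodium_considered}
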