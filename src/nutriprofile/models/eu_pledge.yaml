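# EU Pledge Nutrition Criteria: category-specific thresholds over energy,
# total sugar, fat, saturated fat, sodium, protein, fibre, fruit/veg and
# micronutrients, across 20 product categories.
#
# STRUCTURAL DEFINITION. Only the two sodium thresholds documented in this
# package's sources are filled in (<=300 mg/100 g for milk and milk
# substitutes; <=450 mg/100 g for breakfast cereals). Every criterion marked
# `todo` awaits transcription from the model's published criteria document;
# until then the registry flags this model incomplete and it is excluded
# from classification runs. Category identities other than the two named
# ones are placeholders pending the same transcription.
model_id: eu_pledge
name: EU Pledge Nutrition Criteria
mode: threshold
categories:
  - category_id: milk_and_milk_substitutes
    priority: 10
    match: {tags_any: [milk, milk_substitute]}
    criteria:
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", threshold: 300, unit: mg}
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: breakfast_cereals
    priority: 20
    match: {tags_any: [breakfast_cereal]}
    criteria:
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", threshold: 450, unit: mg}
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: fibre_g, basis: per_100g, comparator: ">=", todo: true}
  - category_id: pending_category_03
    priority: 30
    match: {tags_any: [eu_pledge_cat_03]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_04
    priority: 40
    match: {tags_any: [eu_pledge_cat_04]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_05
    priority: 50
    match: {tags_any: [eu_pledge_cat_05]}
    criteria:
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: fruit_veg_nut_pct, basis: per_100g, comparator: ">=", todo: true}
  - category_id: pending_category_06
    priority: 60
    match: {tags_any: [eu_pledge_cat_06]}
    criteria:
      - {nutrient: protein_g, basis: per_100g, comparator: ">=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_07
    priority: 70
    match: {tags_any: [eu_pledge_cat_07]}
    criteria:
      - {nutrient: micronutrient_count, basis: per_100g, comparator: ">=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_08
    priority: 80
    match: {tags_any: [eu_pledge_cat_08]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_09
    priority: 90
    match: {tags_any: [eu_pledge_cat_09]}
    criteria:
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_10
    priority: 100
    match: {tags_any: [eu_pledge_cat_10]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_11
    priority: 110
    match: {tags_any: [eu_pledge_cat_11]}
    criteria:
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_12
    priority: 120
    match: {tags_any: [eu_pledge_cat_12]}
    criteria:
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_13
    priority: 130
    match: {tags_any: [eu_pledge_cat_13]}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_14
    priority: 140
    match: {tags_any: [eu_pledge_cat_14]}
    criteria:
      - {nutrient: fibre_g, basis: per_100g, comparator: ">=", todo: true}
  - category_id: pending_category_15
    priority: 150
    match: {tags_any: [eu_pledge_cat_15]}
    criteria:
      - {nutrient: fruit_veg_nut_pct, basis: per_100g, comparator: ">=", todo: true}
  - category_id: pending_category_16
    priority: 160
    match: {tags_any: [eu_pledge_cat_16]}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
  - category_id: pending_category_17
    priority: 170
    match: {tags_any: [eu_pledge_cat_17]}
    criteria:
      - {nutrient: total_fat_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: pending_category_18
    priority: 180
    match: {tags_any: [eu_pledge_cat_18]}
    criteria:
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
  - category_id: drinks
    priority: 190
    match: {is_drink: true}
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
  - category_id: other_foods
    priority: 200
    criteria:
      - {nutrient: energy_kcal, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
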