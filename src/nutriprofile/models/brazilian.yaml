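# Brazilian model: thresholds on total sugar, saturated fat, trans fat and
# sodium, with separate criteria for foods and drinks (2 categories).
#
# STRUCTURAL DEFINITION: numeric thresholds pending transcription from the
# model's source documentation; the registry flags this model incomplete and
# excludes it from classification runs until they are filled in.
model_id: brazilian
name: Brazilian model
mode: threshold
categories:
  - category_id: drinks
    priority: 10
    match: {is_drink: true}
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
  - category_id: foods
    priority: 20
    criteria:
      - {nutrient: total_sugar_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_100g, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_100g, comparator: "<=", todo: true}
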