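# US Interagency Working Group model: criteria on added sugar, saturated
# fat, trans fat, sodium and fruit/vegetable content, with 2 categories.
#
# STRUCTURAL DEFINITION: numeric thresholds pending transcription from the
# model's source documentation; the registry flags this model incomplete and
# excludes it from classification runs.
model_id: us_interagency
name: US Interagency Working Group model
mode: threshold
categories:
  - category_id: drinks
    priority: 10
    match: {is_drink: true}
    criteria:
      - {nutrient: added_sugar_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
  - category_id: foods
    priority: 20
    criteria:
      - {nutrient: added_sugar_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: saturated_fat_g, basis: pct_energy, comparator: "<=", todo: true}
      - {nutrient: trans_fat_g, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: sodium_mg, basis: per_serving, comparator: "<=", todo: true}
      - {nutrient: fruit_veg_nut_pct, basis: per_100g, comparator: ">=", todo: true}
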