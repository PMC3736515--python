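# UK FSA/Ofcom nutrient profiling model (2004/05 scheme as used for the
# broadcast advertising regulations). Points-based: A-points for energy,
# saturated fat, total sugar and sodium; C-points for fruit/veg/nuts, fibre
# and protein; score = A - C. A food scores points per strict lower bound
# exceeded (">" bands, per the official technical guidance). "Less healthy"
# (not permitted) at score >= 4 for foods, >= 1 for drinks.
model_id: uk
name: UK FSA/Ofcom nutrient profiling model
mode: points
points:
  # A-components, per 100 g: 1..10 points for values strictly above each bound.
  energy_kJ: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  saturated_fat_g: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  total_sugar_g: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
  sodium_mg: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
  # C-components. Fruit/veg/nuts scores 1, 2 or 5 points; fibre bands depend
  # on the assay method behind the declared value.
  fruit_veg_nut_pct: [[40, 1], [60, 2], [80, 5]]
  fibre_g:
    NSP: [0.7, 1.4, 2.1, 2.8, 3.5]
    AOAC: [0.9, 1.9, 2.8, 3.7, 4.7]
  protein_g: [1.6, 3.2, 4.8, 6.4, 8.0]
  # Protein may only be credited when A-points < 11, unless fruit/veg/nuts
  # scores the maximum 5 points.
  protein_bar_a_points: 11
  protein_bar_fvn_exempt: 5
  fail_threshold_food: 4
  fail_threshold_drink: 1
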