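# Per-category nutrient sampling parameters for the synthetic advertised-food
# generator. Each nutrient entry is [median, sigma, max]: values are drawn as
# median * exp(sigma * Z) with Z standard normal (a log-normal, so strictly
# non-negative and right-skewed like real composition data) and clipped to
# max. total_fat_g is derived as saturated + unsaturated fat;
# trans_fat_g and added_sugar_g are derived fractions of saturated fat and
# total sugar. serving_size_g is drawn the same way (min 10 g).
# Parameters are chosen so each category spans the pass/fail boundaries of
# the scoring bands (e.g. cereals straddling the sugar bands, snacks far
# beyond them, drinks around the zero-score neighbourhood).
bread_cereals_potatoes:
  energy_kJ: [1450, 0.35, 3400]
  total_sugar_g: [12, 0.9, 70]
  saturated_fat_g: [1.2, 0.9, 25]
  unsat_fat_g: [2.5, 0.8, 30]
  sodium_mg: [350, 0.9, 1800]
  protein_g: [8, 0.4, 25]
  fibre_g: [3, 0.6, 15]
  fruit_veg_nut_pct: [1.5, 1.5, 100]
  cholesterol_mg: [5, 1.0, 150]
  serving_size_g: [40, 0.4, 400]
composite:
  energy_kJ: [800, 0.4, 2500]
  total_sugar_g: [4, 1.0, 40]
  saturated_fat_g: [3, 0.7, 20]
  unsat_fat_g: [4, 0.7, 25]
  sodium_mg: [420, 0.6, 1600]
  protein_g: [7, 0.4, 25]
  fibre_g: [1.5, 0.7, 10]
  fruit_veg_nut_pct: [15, 1.0, 100]
  cholesterol_mg: [25, 0.8, 200]
  serving_size_g: [300, 0.3, 600]
fruit_veg:
  energy_kJ: [260, 0.6, 1500]
  total_sugar_g: [6, 0.8, 25]
  saturated_fat_g: [0.1, 0.9, 3]
  unsat_fat_g: [0.3, 0.9, 5]
  sodium_mg: [15, 1.1, 400]
  protein_g: [1.5, 0.6, 8]
  fibre_g: [2.5, 0.5, 10]
  fruit_veg_nut_pct: [90, 0.12, 100]
  cholesterol_mg: [0, 0, 0]
  serving_size_g: [80, 0.3, 300]
meat_fish_alternatives:
  energy_kJ: [900, 0.4, 2500]
  total_sugar_g: [1.5, 1.0, 15]
  saturated_fat_g: [3.5, 0.7, 18]
  unsat_fat_g: [6, 0.6, 25]
  sodium_mg: [600, 0.7, 2000]
  protein_g: [16, 0.3, 35]
  fibre_g: [0.8, 1.0, 6]
  fruit_veg_nut_pct: [2, 1.5, 60]
  cholesterol_mg: [60, 0.6, 300]
  serving_size_g: [100, 0.35, 350]
milk_dairy:
  energy_kJ: [450, 0.55, 2200]
  total_sugar_g: [8, 0.7, 35]
  saturated_fat_g: [2.5, 0.9, 22]
  unsat_fat_g: [1.5, 0.8, 15]
  sodium_mg: [120, 0.9, 1200]
  protein_g: [4, 0.5, 28]
  fibre_g: [0.1, 1.2, 3]
  fruit_veg_nut_pct: [0.5, 1.5, 40]
  cholesterol_mg: [15, 0.8, 120]
  serving_size_g: [150, 0.4, 500]
miscellaneous:
  energy_kJ: [1000, 0.8, 3400]
  total_sugar_g: [15, 1.2, 90]
  saturated_fat_g: [2, 1.2, 30]
  unsat_fat_g: [3, 1.0, 30]
  sodium_mg: [400, 1.2, 2500]
  protein_g: [4, 0.8, 25]
  fibre_g: [1, 1.2, 12]
  fruit_veg_nut_pct: [5, 1.5, 100]
  cholesterol_mg: [10, 1.2, 250]
  serving_size_g: [50, 0.6, 400]
fatty_sugary/snack:
  energy_kJ: [2100, 0.25, 3400]
  total_sugar_g: [35, 0.6, 90]
  saturated_fat_g: [8, 0.7, 35]
  unsat_fat_g: [10, 0.6, 35]
  sodium_mg: [300, 1.1, 2200]
  protein_g: [5, 0.6, 20]
  fibre_g: [1.8, 0.8, 10]
  fruit_veg_nut_pct: [2, 1.5, 80]
  cholesterol_mg: [15, 1.0, 180]
  serving_size_g: [35, 0.4, 150]
fatty_sugary/not_snack:
  energy_kJ: [1700, 0.35, 3400]
  total_sugar_g: [25, 0.8, 90]
  saturated_fat_g: [6, 0.8, 32]
  unsat_fat_g: [8, 0.7, 32]
  sodium_mg: [250, 1.0, 1800]
  protein_g: [4, 0.6, 18]
  fibre_g: [1.2, 0.8, 8]
  fruit_veg_nut_pct: [3, 1.5, 90]
  cholesterol_mg: [20, 1.0, 200]
  serving_size_g: [60, 0.4, 250]
fatty_sugary/drink:
  energy_kJ: [180, 0.5, 900]
  total_sugar_g: [10, 0.6, 25]
  saturated_fat_g: [0.05, 1.0, 2]
  unsat_fat_g: [0.05, 1.0, 2]
  sodium_mg: [30, 1.1, 300]
  protein_g: [0.3, 1.2, 5]
  fibre_g: [0.05, 1.2, 2]
  fruit_veg_nut_pct: [8, 1.5, 100]
  cholesterol_mg: [0, 0, 0]
  serving_size_g: [330, 0.2, 600]
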