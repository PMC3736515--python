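category,serving_size_g
bread_cereals_potatoes,40
fruit_veg,80
meat_fish_alternatives,100
milk_dairy,150
fatty_sugary/snack,35
fatty_sugary/not_snack,60
fatty_sugary/drink,330
composite,300
miscellaneous,50
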