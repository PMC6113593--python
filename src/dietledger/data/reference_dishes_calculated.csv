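dish,nutrient,calculated_per_100g
garlic puree cooked pork leg,energy_kcal,288.1
garlic puree cooked pork leg,protein_g,25
garlic puree cooked pork leg,fat_g,20.9
garlic puree cooked pork leg,carbohydrate_g,0
dry-fried string beans,energy_kcal,210.7
dry-fried string beans,protein_g,9.25
dry-fried string beans,fat_g,18.2
dry-fried string beans,carbohydrate_g,5.73
roast lamb,energy_kcal,133.4
roast lamb,protein_g,19.4
roast lamb,fat_g,6.2
roast lamb,carbohydrate_g,0
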