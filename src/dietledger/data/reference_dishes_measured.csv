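dish,nutrient,measured_per_100g,method
garlic puree cooked pork leg,energy_kcal,253,
garlic puree cooked pork leg,protein_g,22,Kjeldahl nitrogen
garlic puree cooked pork leg,fat_g,18.3,acid hydrolysis
garlic puree cooked pork leg,carbohydrate_g,0,
dry-fried string beans,energy_kcal,229,
dry-fried string beans,protein_g,10.8,Kjeldahl nitrogen
dry-fried string beans,fat_g,16.7,acid hydrolysis
dry-fried string beans,carbohydrate_g,9,
roast lamb,energy_kcal,162,
roast lamb,protein_g,21.5,Kjeldahl nitrogen
roast lamb,fat_g,8.1,acid hydrolysis
roast lamb,carbohydrate_g,0.8,
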