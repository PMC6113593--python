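{
  "schema_version": 1,
  "source": "reference-dish recipes; ingredient lists and preparation methods as published, raw weights synthetic (the originals are not public)",
  "recipes": [
    {
      "dish": "garlic puree cooked pork leg",
      "dish_type": "cooked",
      "method": "steam",
      "ingredients": [
        {"name": "pork", "weight_g": 500, "auxiliary": false},
        {"name": "garlic", "weight_g": 20, "auxiliary": true},
        {"name": "scallions", "weight_g": 10, "auxiliary": true},
        {"name": "pepper", "weight_g": 2, "auxiliary": true}
      ]
    },
    {
      "dish": "dry-fried string beans",
      "dish_type": "cooked",
      "method": "stir-fry",
      "ingredients": [
        {"name": "string beans", "weight_g": 400, "auxiliary": false},
        {"name": "minced pork", "weight_g": 80, "auxiliary": false},
        {"name": "dried chilies", "weight_g": 10, "auxiliary": true},
        {"name": "garlic", "weight_g": 10, "auxiliary": true},
        {"name": "scallions", "weight_g": 10, "auxiliary": true}
      ]
    },
    {
      "dish": "roast lamb",
      "dish_type": "cooked",
      "method": "roast",
      "ingredients": [
        {"name": "lamb", "weight_g": 450, "auxiliary": false},
        {"name": "onion", "weight_g": 60, "auxiliary": false},
        {"name": "oil", "weight_g": 15, "auxiliary": false},
        {"name": "cumin", "weight_g": 5, "auxiliary": true}
      ]
    }
  ]
}
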