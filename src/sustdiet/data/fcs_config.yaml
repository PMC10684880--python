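# Placeholder adapted Food Compass configuration.
#
# Structure is authoritative for this package's adapted scoring: 46
# attributes over 7 domains, red and processed meats as separate
# attributes, and the iodine / trans-fat / medium-chain fatty acid /
# flavonoid / carotenoid attributes and the processing and phytochemical
# domains excluded.  The CUT-POINTS THEMSELVES ARE A NON-AUTHORITATIVE
# PLACEHOLDER: monotone ladders on plausible per-100-kcal scales, intended
# for testing the scoring machinery.  Authoritative cut-points can replace
# this file without code changes.
#
# All attribute values are amounts per 100 kcal of diet.  Ingredient
# attributes are grams of the food group per 100 kcal.

scaling:
  upper: 26.1
  span: 36.7
  range: 99

domains:
  - nutrient ratios
  - vitamins
  - minerals
  - food ingredients
  - additives
  - specific lipids
  - protein & fiber

attributes:
  # --- nutrient ratios (4) ---
  - {name: fiber_carb_ratio, domain: nutrient ratios, direction: beneficial, thresholds: [0.02, 0.05, 0.10], scores: [0, 3, 7, 10]}
  - {name: potassium_sodium_ratio, domain: nutrient ratios, direction: beneficial, thresholds: [0.5, 1.0, 2.0], scores: [0, 3, 7, 10]}
  - {name: unsat_sat_fat_ratio, domain: nutrient ratios, direction: beneficial, thresholds: [1.0, 2.0, 3.0], scores: [0, 3, 7, 10]}
  - {name: sugar_carb_ratio, domain: nutrient ratios, direction: harmful, thresholds: [0.10, 0.25, 0.50], scores: [10, 7, 3, 0]}
  # --- vitamins (12) ---
  - {name: vitamin_a, domain: vitamins, direction: beneficial, thresholds: [30, 60, 120], scores: [0, 3, 7, 10]}
  - {name: vitamin_c, domain: vitamins, direction: beneficial, thresholds: [3, 9, 18], scores: [0, 3, 7, 10]}
  - {name: vitamin_d, domain: vitamins, direction: beneficial, thresholds: [0.5, 1.0, 2.0], scores: [0, 3, 7, 10]}
  - {name: vitamin_e, domain: vitamins, direction: beneficial, thresholds: [0.5, 1.0, 2.0], scores: [0, 3, 7, 10]}
  - {name: vitamin_k, domain: vitamins, direction: beneficial, thresholds: [4, 12, 24], scores: [0, 3, 7, 10]}
  - {name: thiamin, domain: vitamins, direction: beneficial, thresholds: [0.04, 0.08, 0.15], scores: [0, 3, 7, 10]}
  - {name: riboflavin, domain: vitamins, direction: beneficial, thresholds: [0.04, 0.08, 0.15], scores: [0, 3, 7, 10]}
  - {name: niacin, domain: vitamins, direction: beneficial, thresholds: [0.5, 1.0, 2.0], scores: [0, 3, 7, 10]}
  - {name: vitamin_b6, domain: vitamins, direction: beneficial, thresholds: [0.05, 0.10, 0.20], scores: [0, 3, 7, 10]}
  - {name: folate, domain: vitamins, direction: beneficial, thresholds: [13, 27, 53], scores: [0, 3, 7, 10]}
  - {name: vitamin_b12, domain: vitamins, direction: beneficial, thresholds: [0.08, 0.16, 0.32], scores: [0, 3, 7, 10]}
  - {name: choline, domain: vitamins, direction: beneficial, thresholds: [18, 37, 73], scores: [0, 3, 7, 10]}
  # --- minerals (9) ---
  - {name: calcium, domain: minerals, direction: beneficial, thresholds: [43, 87, 173], scores: [0, 3, 7, 10]}
  - {name: iron, domain: minerals, direction: beneficial, thresholds: [0.6, 1.2, 2.4], scores: [0, 3, 7, 10]}
  - {name: magnesium, domain: minerals, direction: beneficial, thresholds: [14, 28, 56], scores: [0, 3, 7, 10]}
  - {name: phosphorus, domain: minerals, direction: beneficial, thresholds: [33, 66, 132], scores: [0, 3, 7, 10]}
  - {name: potassium, domain: minerals, direction: beneficial, thresholds: [156, 313, 626], scores: [0, 3, 7, 10]}
  - {name: zinc, domain: minerals, direction: beneficial, thresholds: [0.37, 0.73, 1.47], scores: [0, 3, 7, 10]}
  - {name: copper, domain: minerals, direction: beneficial, thresholds: [0.03, 0.06, 0.12], scores: [0, 3, 7, 10]}
  - {name: selenium, domain: minerals, direction: beneficial, thresholds: [1.8, 3.7, 7.3], scores: [0, 3, 7, 10]}
  - {name: manganese, domain: minerals, direction: beneficial, thresholds: [0.08, 0.15, 0.31], scores: [0, 3, 7, 10]}
  # --- food ingredients (13, grams of group per 100 kcal) ---
  - {name: whole grains, domain: food ingredients, direction: beneficial, thresholds: [5, 15], scores: [0, 1, 2]}
  - {name: nuts, domain: food ingredients, direction: beneficial, thresholds: [2, 5], scores: [0, 1, 2]}
  - {name: legumes, domain: food ingredients, direction: beneficial, thresholds: [5, 15], scores: [0, 1, 2]}
  - {name: fruits, domain: food ingredients, direction: beneficial, thresholds: [20, 50], scores: [0, 1, 2]}
  - {name: vegetables, domain: food ingredients, direction: beneficial, thresholds: [20, 50], scores: [0, 1, 2]}
  - {name: fish/seafood, domain: food ingredients, direction: beneficial, thresholds: [5, 15], scores: [0, 1, 2]}
  - {name: red meat, domain: food ingredients, direction: harmful, thresholds: [4.0], scores: [1, 0]}
  - {name: processed meat, domain: food ingredients, direction: harmful, thresholds: [2.0], scores: [1, 0]}
  - {name: sugar-sweetened beverages, domain: food ingredients, direction: harmful, thresholds: [30], scores: [1, 0]}
  - {name: refined grains, domain: food ingredients, direction: harmful, thresholds: [25], scores: [1, 0]}
  - {name: white meat, domain: food ingredients, direction: harmful, thresholds: [10], scores: [1, 0]}
  - {name: dairy, domain: food ingredients, direction: beneficial, thresholds: [20], scores: [0, 1]}
  - {name: eggs, domain: food ingredients, direction: beneficial, thresholds: [4], scores: [0, 1]}
  # --- additives (2; typically unpopulated: raw composite diets) ---
  - {name: artificial_sweeteners, domain: additives, direction: harmful, thresholds: [0.01, 0.10], scores: [10, 5, 0]}
  - {name: sodium_preservatives, domain: additives, direction: harmful, thresholds: [0.01, 0.10], scores: [10, 5, 0]}
  # --- specific lipids (4) ---
  - {name: cholesterol, domain: specific lipids, direction: harmful, thresholds: [20, 60, 150], scores: [10, 7, 3, 0]}
  - {name: ala, domain: specific lipids, direction: beneficial, thresholds: [0.05, 0.10, 0.20], scores: [0, 3, 7, 10]}
  - {name: epa, domain: specific lipids, direction: beneficial, thresholds: [0.01, 0.05, 0.10], scores: [0, 3, 7, 10]}
  - {name: dha, domain: specific lipids, direction: beneficial, thresholds: [0.01, 0.05, 0.10], scores: [0, 3, 7, 10]}
  # --- protein & fiber (2) ---
  - {name: protein, domain: protein & fiber, direction: beneficial, thresholds: [2, 4, 8], scores: [0, 3, 7, 10]}
  - {name: fiber, domain: protein & fiber, direction: beneficial, thresholds: [0.7, 1.4, 2.8], scores: [0, 3, 7, 10]}
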