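# Synthetic default scoring table for the modified Healthy Food Intake
# Index (mHFII).
#
# The published cut-off table of the study index is not available in
# machine-readable form, so these thresholds are a constructed stand-in
# that satisfies every documented structural constraint:
#   * 11 components; 7 carry max 2 points and 4 carry max 1 point
#     (total score range 0-18);
#   * favourable components award points for frequent consumption,
#     limiting components for infrequent consumption;
#   * thresholds are weekly frequencies (times/week) reachable as sums of
#     the 7-level conversion values {0, 0.12, 0.47, 1.5, 4, 6, 8} over the
#     component's member items, oriented on Nordic food-based dietary
#     guidelines (daily vegetables/fruit, fish 2-3 times/week, limits on
#     red and processed meat and sugar-sweetened beverages).
#
# Boundary convention: a weekly frequency exactly AT a threshold falls in
# the higher-scoring band ("at least" for favourable components, "at
# most" for limiting ones).
name: mhfii-default-synthetic
components:
  - name: vegetables
    direction: favourable
    max_points: 2
    thresholds: [4, 6]        # >=4 /wk -> 1 pt, >=6 /wk -> 2 pt
    items: [fresh_vegetables, cooked_vegetables, vegetable_dishes, legumes]
  - name: fruits_berries
    direction: favourable
    max_points: 2
    thresholds: [2, 6]
    items: [fresh_fruits, berries, fruit_berry_dishes]
  - name: fibre_rich_grains
    direction: favourable
    max_points: 2
    thresholds: [6, 12]
    items: [rye_bread, wholegrain_bread, porridge, breakfast_cereals]
  - name: fish
    direction: favourable
    max_points: 2
    thresholds: [1.5, 3]
    items: [fish_dishes, fish_cold_cuts]
  - name: milk
    direction: favourable
    max_points: 2
    thresholds: [4, 6]
    items: [skimmed_milk, sour_milk]
  - name: red_processed_meat
    direction: limiting
    max_points: 2
    thresholds: [1.5, 4]      # <=1.5 /wk -> 2 pt, <=4 /wk -> 1 pt
    items: [red_meat_dishes, processed_meat_dishes, cold_cuts_sausage]
  - name: sugar_sweetened_beverages
    direction: limiting
    max_points: 2
    thresholds: [0.47, 1.5]
    items: [sugary_soft_drinks, energy_drinks, sugary_juice_drinks]
  - name: vegetable_oil
    direction: favourable
    max_points: 1
    thresholds: [4]
    items: [cooking_oil, oil_based_dressing]
  - name: nuts_seeds
    direction: favourable
    max_points: 1
    thresholds: [4]
    items: [nuts_unsalted, seeds]
  - name: fat_spreads
    direction: favourable
    max_points: 1
    thresholds: [6]
    items: [vegetable_fat_spread]
  - name: snacks
    direction: limiting
    max_points: 1
    thresholds: [1.5]
    items: [sweets_chocolate, salty_snacks, sweet_pastry, ice_cream]
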