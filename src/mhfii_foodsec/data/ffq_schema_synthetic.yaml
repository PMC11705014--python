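# Synthetic 52-item FFQ schema.
#
# The study instrument's exact item list is not publicly deposited; this
# file is a constructed stand-in with the documented structure: 52 items,
# 30 of which belong to the 11 diet-quality index components (see
# scoring_table_synthetic.yaml) and 22 of which (beverages, alcohol,
# dairy/meat items outside the index...) are parsed and carried through
# but never scored.
#
# Cells are coded on the 7-level scale:
#   0 not at all | 1 less than once a month | 2 1-3 d per month
#   3 1-2 d per week | 4 3-5 d per week | 5 daily or almost daily
#   6 more than once a day
items:
  # vegetables
  - fresh_vegetables
  - cooked_vegetables
  - vegetable_dishes
  - legumes
  # fruits and berries
  - fresh_fruits
  - berries
  - fruit_berry_dishes
  # fibre-rich grains
  - rye_bread
  - wholegrain_bread
  - porridge
  - breakfast_cereals
  # fish
  - fish_dishes
  - fish_cold_cuts
  # milk
  - skimmed_milk
  - sour_milk
  # red and processed meat
  - red_meat_dishes
  - processed_meat_dishes
  - cold_cuts_sausage
  # sugar-sweetened beverages
  - sugary_soft_drinks
  - energy_drinks
  - sugary_juice_drinks
  # vegetable oil
  - cooking_oil
  - oil_based_dressing
  # nuts and seeds
  - nuts_unsalted
  - seeds
  # fat spreads
  - vegetable_fat_spread
  # snacks
  - sweets_chocolate
  - salty_snacks
  - sweet_pastry
  - ice_cream
  # unscored items (22)
  - cheese
  - yogurt
  - whole_milk
  - cream
  - eggs
  - poultry
  - white_bread
  - white_rice_pasta
  - potatoes
  - butter
  - butter_oil_blend
  - soy_vegetarian_dishes
  - fruit_juice
  - coffee
  - tea
  - bottled_water
  - wine
  - beer
  - cider
  - alcohol_free_beer
  - alcohol_free_cider
  - spirits
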