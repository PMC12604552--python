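# Default food-group-specific acceptable Nutri-Score ranges for school food
# procurement, aligned with the Norwegian school meal guidelines.
# Rules are evaluated in order; the first matching rule decides.
name: nutriscore-2023-school
default_letters: [A, B]
rules:
  - id: fish-bread-topping
    match: {role: bread topping, food_group: Fish and seafood}
    letters: [A, B, C, D]
    citation: "D acceptable for fish-based bread toppings"
  - id: bread-topping
    match: {role: bread topping}
    letters: [A, B, C]
    citation: "C acceptable for bread toppings"
  - id: juice-small-portion
    match: {role: juice, max_portion_ml: 250}
    letters: [A, B, C]
    citation: "C acceptable for juice in portions not exceeding 250 ml"
  - id: small-quantity-ingredient
    match: {role: small-quantity ingredient}
    letters: [A, B, C, D]
    citation: "D acceptable for ingredients used in small quantities (dressings, reduced-fat cream, mayonnaise)"
  - id: oil-based-dressing
    match: {role: oil-based dressing}
    letters: [A, B, C, D, E]
    citation: "E acceptable only for oil-based salad dressings"
whole_grain_advisory:
  # advisory annotation, never a verdict change: prefer whole grain over
  # refined products of flour, rice and pasta
  food_groups: [Bread, Grains, Pasta and rice]
  note: "prefer whole grain over refined flour, rice and pasta"
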