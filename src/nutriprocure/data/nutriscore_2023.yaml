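# Nutri-Score point tables and letter cutoffs, 2023 algorithm revision
# ("nutriscore-2023"). Three algorithm classes: general foods; fats, oils,
# nuts and seeds; beverages. Points are step functions of the nutrient
# amount per 100 g (foods) or 100 ml (beverages).
#
# mode: gt  -> a step is earned when value >  threshold (default)
# mode: ge  -> a step is earned when value >= threshold (ratio table only)
version: nutriscore-2023

general:
  negative:
    energy_kj:
      unit: kJ/100g
      steps: [[335, 1], [670, 2], [1005, 3], [1340, 4], [1675, 5],
              [2010, 6], [2345, 7], [2680, 8], [3015, 9], [3350, 10]]
      cap: 10
    sugars_g:
      unit: g/100g
      steps: [[3.4, 1], [6.8, 2], [10, 3], [14, 4], [17, 5], [20, 6],
              [24, 7], [27, 8], [31, 9], [34, 10], [37, 11], [41, 12],
              [44, 13], [48, 14], [51, 15]]
      cap: 15
    saturated_fat_g:
      unit: g/100g
      steps: [[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 6], [7, 7],
              [8, 8], [9, 9], [10, 10]]
      cap: 10
    salt_g:
      unit: g/100g
      steps: [[0.2, 1], [0.4, 2], [0.6, 3], [0.8, 4], [1.0, 5], [1.2, 6],
              [1.4, 7], [1.6, 8], [1.8, 9], [2.0, 10], [2.2, 11], [2.4, 12],
              [2.6, 13], [2.8, 14], [3.0, 15], [3.2, 16], [3.4, 17],
              [3.6, 18], [3.8, 19], [4.0, 20]]
      cap: 20
  positive:
    protein_g:
      unit: g/100g
      steps: [[2.4, 1], [4.8, 2], [7.2, 3], [9.6, 4], [12, 5], [14, 6], [17, 7]]
      cap: 7
    fiber_g:
      unit: g/100g
      steps: [[3.0, 1], [4.1, 2], [5.2, 3], [6.3, 4], [7.4, 5]]
      cap: 5
    fvl_percent:
      unit: "%"
      steps: [[40, 1], [60, 2], [80, 5]]
      cap: 5
  protein_rule:
    # protein points dropped when N >= threshold, unless the product is a
    # cheese or the fruit/vegetable/legume component is at its cap
    negative_threshold: 11
    cheese_exempt: true
    fvl_max_exempt: true
    red_meat_protein_cap: 2
  cutoffs:
    # letter applies when final score <= bound; E is the unbounded remainder
    A: 0
    B: 2
    C: 10
    D: 18

fats_oils_nuts_seeds:
  negative:
    energy_from_saturates_kj:
      # saturated fat (g) x 37 kJ/g
      unit: kJ/100g
      steps: [[120, 1], [240, 2], [360, 3], [480, 4], [600, 5], [720, 6],
              [840, 7], [960, 8], [1080, 9], [1200, 10]]
      cap: 10
    sugars_g:
      unit: g/100g
      steps: [[3.4, 1], [6.8, 2], [10, 3], [14, 4], [17, 5], [20, 6],
              [24, 7], [27, 8], [31, 9], [34, 10], [37, 11], [41, 12],
              [44, 13], [48, 14], [51, 15]]
      cap: 15
    saturates_ratio_percent:
      # saturated fat / total fat x 100
      unit: "%"
      mode: ge
      steps: [[10, 1], [16, 2], [22, 3], [28, 4], [34, 5], [40, 6],
              [46, 7], [52, 8], [58, 9], [64, 10]]
      cap: 10
    salt_g:
      unit: g/100g
      steps: [[0.2, 1], [0.4, 2], [0.6, 3], [0.8, 4], [1.0, 5], [1.2, 6],
              [1.4, 7], [1.6, 8], [1.8, 9], [2.0, 10], [2.2, 11], [2.4, 12],
              [2.6, 13], [2.8, 14], [3.0, 15], [3.2, 16], [3.4, 17],
              [3.6, 18], [3.8, 19], [4.0, 20]]
      cap: 20
  positive:
    protein_g:
      unit: g/100g
      steps: [[2.4, 1], [4.8, 2], [7.2, 3], [9.6, 4], [12, 5], [14, 6], [17, 7]]
      cap: 7
    fiber_g:
      unit: g/100g
      steps: [[3.0, 1], [4.1, 2], [5.2, 3], [6.3, 4], [7.4, 5]]
      cap: 5
    fvl_percent:
      unit: "%"
      steps: [[40, 1], [60, 2], [80, 5]]
      cap: 5
  protein_rule:
    negative_threshold: 7
    cheese_exempt: true
    fvl_max_exempt: true
    red_meat_protein_cap: 2
  cutoffs:
    A: -6
    B: 2
    C: 10
    D: 18

beverage:
  negative:
    energy_kj:
      unit: kJ/100ml
      steps: [[30, 1], [90, 2], [150, 3], [210, 4], [240, 5], [270, 6],
              [300, 7], [330, 8], [360, 9], [390, 10]]
      cap: 10
    sugars_g:
      unit: g/100ml
      steps: [[0.5, 1], [2, 2], [3.5, 3], [5, 4], [6, 5], [7, 6], [8, 7],
              [9, 8], [10, 9], [11, 10]]
      cap: 10
    saturated_fat_g:
      unit: g/100ml
      steps: [[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 6], [7, 7],
              [8, 8], [9, 9], [10, 10]]
      cap: 10
    salt_g:
      unit: g/100ml
      steps: [[0.2, 1], [0.4, 2], [0.6, 3], [0.8, 4], [1.0, 5], [1.2, 6],
              [1.4, 7], [1.6, 8], [1.8, 9], [2.0, 10], [2.2, 11], [2.4, 12],
              [2.6, 13], [2.8, 14], [3.0, 15], [3.2, 16], [3.4, 17],
              [3.6, 18], [3.8, 19], [4.0, 20]]
      cap: 20
  sweetener_points: 4
  positive:
    protein_g:
      unit: g/100ml
      steps: [[1.2, 1], [1.5, 2], [1.8, 3], [2.1, 4], [2.4, 5], [2.7, 6], [3.0, 7]]
      cap: 7
    fiber_g:
      unit: g/100ml
      steps: [[3.0, 1], [4.1, 2], [5.2, 3], [6.3, 4], [7.4, 5]]
      cap: 5
    fvl_percent:
      unit: "%"
      steps: [[40, 2], [60, 4], [80, 6]]
      cap: 6
  # beverage protein always counts; no negative-point exclusion rule
  cutoffs:
    # water is always A; no other beverage can reach A
    B: 2
    C: 6
    D: 9
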