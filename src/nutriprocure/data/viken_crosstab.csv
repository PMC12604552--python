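food_group,band,recommended,limited,not_recommended
Overall,A-B,1791,271,24
Overall,C,368,471,167
Overall,D-E,375,844,479
Fruits and vegetables,A-B,1140,16,0
Fruits and vegetables,C,54,11,0
Fruits and vegetables,D-E,59,54,1
Grains,A-B,62,24,0
Grains,C,10,8,0
Grains,D-E,0,8,0
Bread,A-B,59,24,0
Bread,C,38,126,3
Bread,D-E,8,38,1
Pasta and rice,A-B,24,75,0
Pasta and rice,C,2,9,0
Pasta and rice,D-E,0,1,0
Red meat,A-B,5,54,0
Red meat,C,0,91,0
Red meat,D-E,1,309,0
White meat,A-B,47,32,0
White meat,C,9,17,0
White meat,D-E,3,44,0
Fish and seafood,A-B,121,1,0
Fish and seafood,C,39,1,0
Fish and seafood,D-E,55,1,0
Ready meals,A-B,51,15,2
Ready meals,C,78,69,14
Ready meals,D-E,28,30,26
Sauces and dressings,A-B,42,4,0
Sauces and dressings,C,57,16,0
Sauces and dressings,D-E,157,56,0
Dairy products and eggs,A-B,57,9,2
Dairy products and eggs,C,20,47,0
Dairy products and eggs,D-E,25,227,0
Fats,A-B,38,1,3
Fats,C,26,4,0
Fats,D-E,22,33,1
Nuts,A-B,40,3,0
Nuts,C,7,18,3
Nuts,D-E,0,2,0
Snacks,A-B,1,0,8
Snacks,C,0,12,72
Snacks,D-E,0,9,343
Beverages,A-B,104,13,9
Beverages,C,28,42,75
Beverages,D-E,17,21,107
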