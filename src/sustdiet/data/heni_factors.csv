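risk,factor,unit
calcium,-5.1000,per g per 100 kcal
polyunsaturated fatty acids,-0.6000,per g per 100 kcal
sodium,13.9000,per g per 100 kcal
trans fats,4.4000,per g per 100 kcal
whole grains,-0.3400,per g per 100 kcal
nuts and seeds,-1.5000,per g per 100 kcal
legumes,-0.2300,per g per 100 kcal
vegetables,-0.0830,per g per 100 kcal
fruits,-0.1800,per g per 100 kcal
seafood,-81.000,per g per 100 kcal
processed meats,0.8600,per g per 100 kcal
red meats,0.0990,per g per 100 kcal
milk,-0.0077,per g per 100 kcal
fiber,-0.1900,per g per 100 kcal
sugar-sweetened beverages,0.0660,per g per 100 kcal
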