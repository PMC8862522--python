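code,display_name,unit,category,direction
protein,Protein,g/kg,macronutrient,target
carbohydrate,Carbohydrate,%energy,macronutrient,target
total_fat,Total fat,%energy,macronutrient,target
saturated_fat,Saturated fat,%energy,macronutrient,limit
monounsaturated_fat,Monounsaturated fat,%energy,macronutrient,target
polyunsaturated_fat,Polyunsaturated fat,%energy,macronutrient,target
energy,Energy,kcal,macronutrient,target
fiber,Dietary fiber,g,macronutrient,adequacy
cholesterol,Cholesterol,mg,macronutrient,limit
vitamin_a,Vitamin A (RAE),ug,vitamin,target
thiamin,Thiamin (B1),mg,vitamin,adequacy
riboflavin,Riboflavin (B2),mg,vitamin,adequacy
niacin,Niacin,mg,vitamin,target
pantothenic_acid,Pantothenic acid (B5),mg,vitamin,adequacy
vitamin_b6,Vitamin B6,mg,vitamin,target
folate,Folate (B9; DFE),ug,vitamin,target
vitamin_b12,Vitamin B12,ug,vitamin,adequacy
vitamin_c,Vitamin C,mg,vitamin,target
vitamin_d,Vitamin D,ug,vitamin,target
vitamin_e,Vitamin E,mg,vitamin,target
vitamin_k,Vitamin K,ug,vitamin,adequacy
calcium,Calcium,mg,mineral,target
chloride,Chloride,mg,mineral,target
iron,Iron,mg,mineral,target
magnesium,Magnesium,mg,mineral,adequacy
manganese,Manganese,mg,mineral,target
phosphorus,Phosphorus,mg,mineral,target
sodium,Sodium,mg,mineral,target
potassium,Potassium,mg,mineral,adequacy
selenium,Selenium,ug,mineral,target
zinc,Zinc,mg,mineral,target
alcohol,Alcohol,g,other,limit
sugar,Total sugars,%energy,other,limit
caffeine,Caffeine,mg,other,limit
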