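nutrient,sex,age_min,age_max,pregnant,lactating,lower,upper,basis,unit
protein,any,9,13,0,0,0.95,,RDA,g/kg
protein,any,14,18,0,0,0.85,,RDA,g/kg
protein,any,19,70,0,0,0.8,,RDA,g/kg
protein,female,19,50,1,0,1.1,,RDA,g/kg
protein,female,19,50,0,1,1.3,,RDA,g/kg
carbohydrate,any,9,70,0,0,45,65,AMDR,%energy
total_fat,any,9,18,0,0,25,35,AMDR,%energy
total_fat,any,19,70,0,0,20,35,AMDR,%energy
saturated_fat,any,9,70,0,0,,10,FDA-limit,%energy
monounsaturated_fat,any,9,70,0,0,10,20,AI,%energy
polyunsaturated_fat,any,9,70,0,0,5,10,AI,%energy
fiber,male,9,13,0,0,31,,AI,g
fiber,male,14,50,0,0,38,,AI,g
fiber,male,51,70,0,0,30,,AI,g
fiber,female,9,18,0,0,26,,AI,g
fiber,female,19,50,0,0,25,,AI,g
fiber,female,51,70,0,0,21,,AI,g
fiber,female,19,50,1,0,28,,AI,g
fiber,female,19,50,0,1,29,,AI,g
cholesterol,any,9,70,0,0,,300,FDA-limit,mg
vitamin_a,male,9,13,0,0,600,1700,RDA,ug
vitamin_a,male,14,18,0,0,900,2800,RDA,ug
vitamin_a,male,19,70,0,0,900,3000,RDA,ug
vitamin_a,female,9,13,0,0,600,1700,RDA,ug
vitamin_a,female,14,18,0,0,700,2800,RDA,ug
vitamin_a,female,19,70,0,0,700,3000,RDA,ug
vitamin_a,female,19,50,1,0,770,3000,RDA,ug
vitamin_a,female,19,50,0,1,1300,3000,RDA,ug
thiamin,male,9,13,0,0,0.9,,RDA,mg
thiamin,male,14,70,0,0,1.2,,RDA,mg
thiamin,female,9,13,0,0,0.9,,RDA,mg
thiamin,female,14,18,0,0,1.0,,RDA,mg
thiamin,female,19,70,0,0,1.1,,RDA,mg
thiamin,female,19,50,1,0,1.4,,RDA,mg
thiamin,female,19,50,0,1,1.4,,RDA,mg
riboflavin,male,9,13,0,0,0.9,,RDA,mg
riboflavin,male,14,70,0,0,1.3,,RDA,mg
riboflavin,female,9,13,0,0,0.9,,RDA,mg
riboflavin,female,14,18,0,0,1.0,,RDA,mg
riboflavin,female,19,70,0,0,1.1,,RDA,mg
riboflavin,female,19,50,1,0,1.4,,RDA,mg
riboflavin,female,19,50,0,1,1.6,,RDA,mg
niacin,male,9,13,0,0,12,20,RDA,mg
niacin,male,14,18,0,0,16,30,RDA,mg
niacin,male,19,70,0,0,16,35,RDA,mg
niacin,female,9,13,0,0,12,20,RDA,mg
niacin,female,14,18,0,0,14,30,RDA,mg
niacin,female,19,70,0,0,14,35,RDA,mg
niacin,female,19,50,1,0,18,35,RDA,mg
niacin,female,19,50,0,1,17,35,RDA,mg
pantothenic_acid,any,9,13,0,0,4,,AI,mg
pantothenic_acid,any,14,70,0,0,5,,AI,mg
pantothenic_acid,female,19,50,1,0,6,,AI,mg
pantothenic_acid,female,19,50,0,1,7,,AI,mg
vitamin_b6,any,9,13,0,0,1.0,60,RDA,mg
vitamin_b6,male,14,18,0,0,1.3,80,RDA,mg
vitamin_b6,male,19,50,0,0,1.3,100,RDA,mg
vitamin_b6,male,51,70,0,0,1.7,100,RDA,mg
vitamin_b6,female,14,18,0,0,1.2,80,RDA,mg
vitamin_b6,female,19,50,0,0,1.3,100,RDA,mg
vitamin_b6,female,51,70,0,0,1.5,100,RDA,mg
vitamin_b6,female,19,50,1,0,1.9,100,RDA,mg
vitamin_b6,female,19,50,0,1,2.0,100,RDA,mg
folate,any,9,13,0,0,300,600,RDA,ug
folate,any,14,18,0,0,400,800,RDA,ug
folate,any,19,70,0,0,400,1000,RDA,ug
folate,female,19,50,1,0,600,1000,RDA,ug
folate,female,19,50,0,1,500,1000,RDA,ug
vitamin_b12,any,9,13,0,0,1.8,,RDA,ug
vitamin_b12,any,14,70,0,0,2.4,,RDA,ug
vitamin_b12,female,19,50,1,0,2.6,,RDA,ug
vitamin_b12,female,19,50,0,1,2.8,,RDA,ug
vitamin_c,any,9,13,0,0,45,1200,RDA,mg
vitamin_c,male,14,18,0,0,75,1800,RDA,mg
vitamin_c,female,14,18,0,0,65,1800,RDA,mg
vitamin_c,male,19,70,0,0,90,2000,RDA,mg
vitamin_c,female,19,70,0,0,75,2000,RDA,mg
vitamin_c,female,19,50,1,0,85,2000,RDA,mg
vitamin_c,female,19,50,0,1,120,2000,RDA,mg
vitamin_d,any,9,70,0,0,15,100,RDA,ug
vitamin_e,any,9,13,0,0,11,600,RDA,mg
vitamin_e,any,14,18,0,0,15,800,RDA,mg
vitamin_e,any,19,70,0,0,15,1000,RDA,mg
vitamin_e,female,19,50,0,1,19,1000,RDA,mg
vitamin_k,any,9,13,0,0,60,,AI,ug
vitamin_k,any,14,18,0,0,75,,AI,ug
vitamin_k,male,19,70,0,0,120,,AI,ug
vitamin_k,female,19,70,0,0,90,,AI,ug
calcium,any,9,18,0,0,1300,3000,RDA,mg
calcium,any,19,50,0,0,1000,2500,RDA,mg
calcium,male,51,70,0,0,1000,2000,RDA,mg
calcium,female,51,70,0,0,1200,2000,RDA,mg
chloride,any,9,13,0,0,2300,3400,AI,mg
chloride,any,14,50,0,0,2300,3600,AI,mg
chloride,any,51,70,0,0,2000,3600,AI,mg
iron,any,9,13,0,0,8,40,RDA,mg
iron,male,14,18,0,0,11,45,RDA,mg
iron,female,14,18,0,0,15,45,RDA,mg
iron,male,19,70,0,0,8,45,RDA,mg
iron,female,19,50,0,0,18,45,RDA,mg
iron,female,51,70,0,0,8,45,RDA,mg
iron,female,19,50,1,0,27,45,RDA,mg
iron,female,19,50,0,1,9,45,RDA,mg
magnesium,male,9,13,0,0,240,,RDA,mg
magnesium,male,14,18,0,0,410,,RDA,mg
magnesium,male,19,30,0,0,400,,RDA,mg
magnesium,male,31,70,0,0,420,,RDA,mg
magnesium,female,9,13,0,0,240,,RDA,mg
magnesium,female,14,18,0,0,360,,RDA,mg
magnesium,female,19,30,0,0,310,,RDA,mg
magnesium,female,31,70,0,0,320,,RDA,mg
magnesium,female,19,30,1,0,350,,RDA,mg
magnesium,female,31,50,1,0,360,,RDA,mg
magnesium,female,19,30,0,1,310,,RDA,mg
magnesium,female,31,50,0,1,320,,RDA,mg
manganese,male,9,13,0,0,1.9,6,AI,mg
manganese,male,14,18,0,0,2.2,9,AI,mg
manganese,male,19,70,0,0,2.3,11,AI,mg
manganese,female,9,13,0,0,1.6,6,AI,mg
manganese,female,14,18,0,0,1.6,9,AI,mg
manganese,female,19,70,0,0,1.8,11,AI,mg
manganese,female,19,50,1,0,2.0,11,AI,mg
manganese,female,19,50,0,1,2.6,11,AI,mg
phosphorus,any,9,18,0,0,1250,4000,RDA,mg
phosphorus,any,19,70,0,0,700,4000,RDA,mg
phosphorus,female,19,50,1,0,700,3500,RDA,mg
sodium,any,9,13,0,0,1200,2200,AI,mg
sodium,any,14,50,0,0,1500,2300,AI,mg
sodium,any,51,70,0,0,1300,2300,AI,mg
potassium,any,9,13,0,0,4500,,AI,mg
potassium,any,14,70,0,0,4700,,AI,mg
potassium,female,19,50,0,1,5100,,AI,mg
selenium,any,9,13,0,0,40,280,RDA,ug
selenium,any,14,70,0,0,55,400,RDA,ug
selenium,female,19,50,1,0,60,400,RDA,ug
selenium,female,19,50,0,1,70,400,RDA,ug
zinc,any,9,13,0,0,8,23,RDA,mg
zinc,male,14,18,0,0,11,34,RDA,mg
zinc,female,14,18,0,0,9,34,RDA,mg
zinc,male,19,70,0,0,11,40,RDA,mg
zinc,female,19,70,0,0,8,40,RDA,mg
zinc,female,19,50,1,0,11,40,RDA,mg
zinc,female,19,50,0,1,12,40,RDA,mg
alcohol,any,9,18,0,0,,0,FDA-limit,g
alcohol,male,19,70,0,0,,28,FDA-limit,g
alcohol,female,19,70,0,0,,14,FDA-limit,g
sugar,any,9,70,0,0,,10,FDA-limit,%energy
caffeine,any,9,18,0,0,,100,FDA-limit,mg
caffeine,any,19,70,0,0,,400,FDA-limit,mg
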