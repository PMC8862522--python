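condition,nutrient,bound,action,amount,unit
smoker,vitamin_c,lower,add,35,mg
hypertension,sodium,upper,set,1500,mg
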