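nutrient_id,driver,stratum_id,value
vitamin_a,income,q1,1.92
vitamin_a,income,q2,1.79
vitamin_a,income,q3,1.29
vitamin_a,income,q4,1.35
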