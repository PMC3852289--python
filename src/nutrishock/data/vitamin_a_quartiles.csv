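stratum_id,weight,mean_intake,cv,baseline_prevalence,cutpoint_value,cutpoint_semantics
q1,0.25,600,,0.457,500,EAR
q2,0.25,800,,0.085,500,EAR
q3,0.25,1200,,0.011,500,EAR
q4,0.25,1500,,0.001,500,EAR
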