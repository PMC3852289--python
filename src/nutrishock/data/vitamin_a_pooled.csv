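stratum_id,weight,mean_intake,baseline_prevalence,cutpoint_value,cutpoint_semantics,elasticity
pooled,1.0,1025,0.095,500,EAR,1.47
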