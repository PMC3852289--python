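z_ref,hr
-3.5,6.0
-2.5,2.6
-1.5,1.6
-0.5,1.0
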