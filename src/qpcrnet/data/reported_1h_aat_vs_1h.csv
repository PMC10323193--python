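gene,p_value,fold_regulation,qc_flag
Aifm1,0.009,-1.29,
Nox4,0.033,-1.65,
Ccl20,0.044,1.68,
Vegfc,0.040,-1.47,
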