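gene,p_value,fold_regulation,qc_flag
Bax,0.008,-1.10,
Cyba,0.022,1.36,
Txnrd2,0.025,-1.25,
Ccl20,0.006,-2.05,
CxCr4,0.025,1.67,
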