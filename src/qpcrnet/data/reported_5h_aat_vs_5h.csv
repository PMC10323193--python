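gene,p_value,fold_regulation,qc_flag
Cyba,0.022,1.40,
Ccl11,0.013,3.00,B
Vcam1,0.041,-2.35,
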