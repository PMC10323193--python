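gene,p_value,fold_regulation,qc_flag
Aifm1,0.014,-1.30,
Bad,0.003,-1.54,
Bcl2,0.010,-1.13,
Casp3,0.002,1.86,
Casp9,0.034,-1.28,
Cflar,0.044,1.81,
Cycs,0.009,-1.25,
Fadd,0.045,1.92,
Fos,0.014,2.29,
Ccs,0.006,-1.31,
Gpx1,0.022,-1.18,
Gpx3,0.005,-1.37,
Gpx4,0.019,-1.15,
Gpx7,0.009,-1.80,
Gstk1,0.003,-1.25,
Hspa1a,0.004,3.70,B
Ncf1,0.025,-1.28,
Nox4,0.005,-1.66,
Prdx1,0.003,-1.21,
Prdx2,0.028,-1.14,
Prdx3,0.043,-1.14,
Sod3,0.039,-1.34,
Txnrd1,0.002,2.33,
Ccl2,0.009,3.92,
Icam1,0.045,2.40,
Tlr4,0.002,-5.85,A
Tollip,0.026,1.24,
Vegfc,0.022,-1.48,
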