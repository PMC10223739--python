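biomarker,mw_g_mol
1-OH-PYR,218.25
Cr,51.996
Cd,112.41
Hg,200.59
Se,78.97
Sb,121.76
As,74.92
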