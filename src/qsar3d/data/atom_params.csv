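element,vdw_radius,well_depth,hydrophobicity
H,1.20,0.042,0.0
C,1.70,0.107,1.0
N,1.55,0.095,-1.0
O,1.52,0.116,-1.0
F,1.47,0.109,1.0
P,1.80,0.314,0.0
S,1.80,0.314,1.0
Cl,1.75,0.240,1.0
Br,1.85,0.320,1.0
I,1.98,0.400,1.0
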