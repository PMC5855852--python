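id,r1_label,r2_label,substitution,split,actual_pEC50,comfa_pred,comsia_pred
01a,unspecified,Et,para,test,5.000,4.996,4.992
02b,unspecified,Et,para,train,5.745,5.650,5.655
03c,unspecified,Et,para,test,5.319,5.483,5.420
04b,unspecified,Et,para,train,4.796,4.915,4.867
05c,unspecified,Et,para,train,4.870,4.869,4.911
06b,unspecified,Et,para,train,5.000,4.941,4.845
07b,unspecified,Et,para,train,5.000,5.015,5.029
08c,unspecified,Et,para,train,5.000,5.039,5.093
09c,unspecified,Et,para,train,5.000,5.019,5.053
10b,unspecified,Et,para,test,5.456,5.174,5.317
11c,unspecified,Et,para,train,5.097,5.090,5.097
12b,unspecified,Et,para,train,4.959,4.874,5.028
13c,unspecified,Et,para,train,5.000,4.924,5.125
14b,unspecified,Et,para,train,5.377,5.261,5.178
15c,unspecified,Et,para,train,5.201,5.315,5.297
16b,unspecified,Et,para,train,5.523,5.588,5.607
17c,unspecified,Et,para,train,5.699,5.645,5.712
18b,unspecified,Et,para,train,5.000,5.060,4.984
19c,unspecified,Et,para,train,5.155,5.121,5.089
20b,unspecified,Et,para,train,5.000,5.182,5.047
21c,unspecified,Et,para,train,5.398,5.239,5.156
22b,unspecified,Et,para,test,5.854,5.846,5.551
23b,unspecified,Et,para,train,5.553,5.615,5.841
24c,unspecified,Et,para,train,6.523,6.542,6.349
25b,unspecified,Et,meta,test,5.000,5.052,4.991
26c,unspecified,Et,meta,test,5.194,5.008,4.983
27b,unspecified,H,para,train,5.000,4.966,4.934
28c,unspecified,H,para,train,5.000,5.002,4.974
29b,unspecified,Me,para,train,5.097,5.151,5.245
30b,unspecified,Pr,para,train,6.046,5.875,5.886
31c,unspecified,Pr,para,train,5.824,5.933,5.993
32b,unspecified,Phenyl,para,train,5.699,5.699,5.648
33c,unspecified,Phenyl,para,train,5.523,5.556,5.439
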