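element,environment,value
H,default,0.667
C,default,1.760
N,default,1.100
O,default,0.802
F,default,0.557
P,default,3.630
S,default,2.900
Cl,default,2.180
Br,default,3.050
I,default,5.350
B,default,3.030
Si,default,5.380
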