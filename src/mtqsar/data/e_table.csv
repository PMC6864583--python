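element,environment,value
H,default,2.20
C,default,2.55
N,default,3.04
O,default,3.44
F,default,3.98
P,default,2.19
S,default,2.58
Cl,default,3.16
Br,default,2.96
I,default,2.66
B,default,2.04
Si,default,1.90
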