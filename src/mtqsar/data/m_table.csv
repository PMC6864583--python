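element,environment,value
H,default,1.008
C,default,12.011
N,default,14.007
O,default,15.999
F,default,18.998
P,default,30.974
S,default,32.06
Cl,default,35.45
Br,default,79.904
I,default,126.904
B,default,10.81
Si,default,28.085
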