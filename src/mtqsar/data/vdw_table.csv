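element,environment,value
H,default,7.238
C,default,20.58
N,default,15.599
O,default,14.71
F,default,13.306
P,default,24.429
S,default,24.429
Cl,default,22.449
Br,default,26.522
I,default,32.515
B,default,29.648
Si,default,38.792
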