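population,haplotype,count
BD,C1,8
CNB,C1,8
CNB,C2,1
CNC,C1,9
CY,C1,10
FQ,C2,9
GM,C1,8
JC,C2,7
MD,C3,12
MJ,C4,9
NE,C2,7
SJ,C1,7
TCB,C5,10
TCD,C6,10
TCH,C7,8
XM,C1,10
YD,C8,9
YJ,C9,7
YJM,C10,8
YJX,C11,9
YX,C2,8
ZY,C12,9
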