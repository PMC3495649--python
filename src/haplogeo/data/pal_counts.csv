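population,haplotype,count
BD,H1,5
BD,H2,1
BD,H3,3
BD,H4,1
CNB,H1,2
CNB,H2,3
CNB,H4,8
CNB,H5,1
CNC,H2,5
CNC,H4,12
CNC,H6,1
CY,H1,4
CY,H2,1
CY,H3,1
CY,H4,6
CY,H6,2
FQ,H2,4
FQ,H4,10
GM,H1,2
GM,H2,3
GM,H3,3
GM,H4,2
JC,H2,1
JC,H4,8
JC,H7,7
MD,H1,2
MD,H3,2
MD,H6,4
MJ,H1,3
MJ,H2,10
MJ,H6,1
NE,H1,4
NE,H2,1
NE,H6,2
NE,H8,9
SJ,H1,2
SJ,H2,3
SJ,H3,1
SJ,H4,6
TCB,H3,2
TCB,H4,1
TCB,H6,9
TCD,H2,1
TCD,H3,3
TCD,H6,10
TCH,H1,2
TCH,H6,7
TCH,H9,3
XM,H2,1
XM,H4,3
XM,H10,2
XM,H11,2
XM,H12,2
YD,H1,4
YD,H2,5
YD,H3,3
YD,H6,1
YD,H13,1
YJ,H1,1
YJ,H2,1
YJ,H4,2
YJ,H14,4
YJ,H15,3
YJ,H16,1
YJM,H2,3
YJM,H3,1
YJM,H4,7
YJM,H6,4
YJM,H17,1
YJX,H2,2
YJX,H3,1
YJX,H10,1
YJX,H17,6
YX,H1,1
YX,H2,6
YX,H4,4
YX,H6,3
ZY,H1,2
ZY,H2,5
ZY,H4,5
ZY,H8,1
ZY,H15,1
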