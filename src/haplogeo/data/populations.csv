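code,latitude,longitude,n_rpl32_trnL,n_pal_individuals
BD,21°50´N,100°06´E,8,5
CNB,24°45´N,99°47´E,9,7
CNC,24°58´N,99°36´E,9,9
CY,23°11´N,99°22´E,10,7
FQ,24°36´N,100°09´E,9,7
GM,23°33´N,99°35´E,8,5
JC,22°30´N,102°01´E,7,8
MD,24°49´N,97°44´E,12,4
MJ,23°11´N,101°43´E,9,7
NE,23°15´N,100°04´E,7,8
SJ,23°41´N,99°47´E,7,6
TCB,24°55´N,98°45´E,10,6
TCD,24°56´N,98°44´E,10,7
TCH,25°17´N,98°07´E,8,6
XM,22°44´N,99°26´E,10,5
YD,24°02´N,99°13´E,9,7
YJ,23°40´N,101°45´E,7,6
YJM,24°49´N,97°56´E,8,8
YJX,24°42´N,97°44´E,9,5
YX,24°39´N,100°19´E,8,7
ZY,24°07´N,101°14´E,9,7
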