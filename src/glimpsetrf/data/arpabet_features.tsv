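phoneme	voiced	unvoiced	sonorant	syllabic	consonantal	approximant	plosive	strident	coronal	anterior	dorsal	front	back	high	low	nasal	fricative	obstruent	bilabial	labiodental	alveolar	velar
AA	1	0	1	1	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0
AE	1	0	1	1	0	0	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0
AH	1	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
AO	1	0	1	1	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0
AW	1	0	1	1	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0
AY	1	0	1	1	0	0	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0
B	1	0	0	0	1	0	1	0	0	1	0	0	0	0	0	0	0	1	1	0	0	0
CH	0	1	0	0	1	0	1	1	1	0	0	0	0	0	0	0	1	1	0	0	0	0
D	1	0	0	0	1	0	1	0	1	1	0	0	0	0	0	0	0	1	0	0	1	0
DH	1	0	0	0	1	0	0	0	1	1	0	0	0	0	0	0	1	1	0	0	0	0
EH	1	0	1	1	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
ER	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
EY	1	0	1	1	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
F	0	1	0	0	1	0	0	1	0	1	0	0	0	0	0	0	1	1	0	1	0	0
G	1	0	0	0	1	0	1	0	0	0	1	0	0	0	0	0	0	1	0	0	0	1
HH	0	1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0
IH	1	0	1	1	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0
IY	1	0	1	1	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0
JH	1	0	0	0	1	0	1	1	1	0	0	0	0	0	0	0	1	1	0	0	0	0
K	0	1	0	0	1	0	1	0	0	0	1	0	0	0	0	0	0	1	0	0	0	1
L	1	0	1	0	1	1	0	0	1	1	0	0	0	0	0	0	0	0	0	0	1	0
M	1	0	1	0	1	0	0	0	0	1	0	0	0	0	0	1	0	0	1	0	0	0
N	1	0	1	0	1	0	0	0	1	1	0	0	0	0	0	1	0	0	0	0	1	0
NG	1	0	1	0	1	0	0	0	0	0	1	0	0	0	0	1	0	0	0	0	0	1
OW	1	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
OY	1	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
P	0	1	0	0	1	0	1	0	0	1	0	0	0	0	0	0	0	1	1	0	0	0
R	1	0	1	0	1	1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
S	0	1	0	0	1	0	0	1	1	1	0	0	0	0	0	0	1	1	0	0	1	0
SH	0	1	0	0	1	0	0	1	1	0	0	0	0	0	0	0	1	1	0	0	0	0
T	0	1	0	0	1	0	1	0	1	1	0	0	0	0	0	0	0	1	0	0	1	0
TH	0	1	0	0	1	0	0	0	1	1	0	0	0	0	0	0	1	1	0	0	0	0
UH	1	0	1	1	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0
UW	1	0	1	1	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0
V	1	0	0	0	1	0	0	1	0	1	0	0	0	0	0	0	1	1	0	1	0	0
W	1	0	1	0	0	1	0	0	0	0	1	0	1	1	0	0	0	0	1	0	0	1
Y	1	0	1	0	0	1	0	0	0	0	1	1	0	1	0	0	0	0	0	0	0	0
Z	1	0	0	0	1	0	0	1	1	1	0	0	0	0	0	0	1	1	0	0	1	0
ZH	1	0	0	0	1	0	0	1	1	0	0	0	0	0	0	0	1	1	0	0	0	0
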