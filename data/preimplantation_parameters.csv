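Gene,Number of activators,Number of repressors,Threshold %
ARGFX,2,0,70
CDX2,3,0,70
DLX5,1,0,80
GATA2,1,0,90
GATA3,1,0,90
GATA4,1,0,80
GATA6,1,0,80
GCM1,2,0,70
HAND1,1,2,70
HNF1B,1,0,80
HNF4A,1,2,60
KLF17,1,1,80
LBH,1,0,70
NANOG,1,0,70
OVOL1,1,0,100
POU5F1,2,0,80
PRDM14,1,1,60
PRDM16,1,0,10
SOX17,2,0,70
SOX2,3,0,80
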