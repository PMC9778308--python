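#grid=8,9
FP1,0,3
FPZ,0,4
FP2,0,5
AF3,0,2
AF4,0,6
F7,1,0
F5,1,1
F3,1,2
F1,1,3
FZ,1,4
F2,1,5
F4,1,6
F6,1,7
F8,1,8
FT7,2,0
FC5,2,1
FC3,2,2
FC1,2,3
FCZ,2,4
FC2,2,5
FC4,2,6
FC6,2,7
FT8,2,8
T7,3,0
C5,3,1
C3,3,2
C1,3,3
CZ,3,4
C2,3,5
C4,3,6
C6,3,7
T8,3,8
TP7,4,0
CP5,4,1
CP3,4,2
CP1,4,3
CPZ,4,4
CP2,4,5
CP4,4,6
CP6,4,7
TP8,4,8
P7,5,0
P5,5,1
P3,5,2
P1,5,3
PZ,5,4
P2,5,5
P4,5,6
P6,5,7
P8,5,8
PO7,6,1
PO5,6,2
PO3,6,3
POZ,6,4
PO4,6,5
PO6,6,6
PO8,6,7
CB1,7,2
O1,7,3
OZ,7,4
O2,7,5
CB2,7,6
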