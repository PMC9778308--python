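#grid=19,19
FP1,1,6
FPZ,1,8
FP2,1,10
AF3,1,4
AF4,1,12
F7,3,0
F5,3,2
F3,3,4
F1,3,6
FZ,3,8
F2,3,10
F4,3,12
F6,3,14
F8,3,16
FT7,5,0
FC5,5,2
FC3,5,4
FC1,5,6
FCZ,5,8
FC2,5,10
FC4,5,12
FC6,5,14
FT8,5,16
T7,7,0
C5,7,2
C3,7,4
C1,7,6
CZ,7,8
C2,7,10
C4,7,12
C6,7,14
T8,7,16
TP7,9,0
CP5,9,2
CP3,9,4
CP1,9,6
CPZ,9,8
CP2,9,10
CP4,9,12
CP6,9,14
TP8,9,16
P7,11,0
P5,11,2
P3,11,4
P1,11,6
PZ,11,8
P2,11,10
P4,11,12
P6,11,14
P8,11,16
PO7,13,2
PO5,13,4
PO3,13,6
POZ,13,8
PO4,13,10
PO6,13,12
PO8,13,14
CB1,15,4
O1,15,6
OZ,15,8
O2,15,10
CB2,15,12
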