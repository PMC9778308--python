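#grid=8,9
Fp1,0,3
AF3,1,3
F3,2,2
F7,2,0
FC5,3,1
FC1,3,3
C3,4,2
T7,4,0
CP5,5,1
CP1,5,3
P3,6,2
P7,6,0
PO3,7,2
O1,7,3
Oz,7,4
Pz,6,4
Fp2,0,5
AF4,1,5
Fz,2,4
F4,2,6
F8,2,8
FC6,3,7
FC2,3,5
Cz,4,4
C4,4,6
T8,4,8
CP6,5,7
CP2,5,5
P4,6,6
P8,6,8
PO4,7,6
O2,7,5
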