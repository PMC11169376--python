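# 9x9 scalp grid for the 32-channel 10-20 montage (row 0 = frontal).
# channel,row,col
Fp1,0,3
Fp2,0,5
AF3,1,3
AF4,1,5
F7,2,0
F3,2,2
Fz,2,4
F4,2,6
F8,2,8
FC5,3,1
FC1,3,3
FC2,3,5
FC6,3,7
T7,4,0
C3,4,2
Cz,4,4
C4,4,6
T8,4,8
CP5,5,1
CP1,5,3
CP2,5,5
CP6,5,7
P7,6,0
P3,6,2
Pz,6,4
P4,6,6
P8,6,8
PO3,7,3
PO4,7,5
O1,8,3
Oz,8,4
O2,8,5
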