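# 9x9 scalp grid for the 14-channel Emotiv EPOC montage (row 0 = frontal).
# channel,row,col
AF3,1,3
AF4,1,5
F7,2,0
F3,2,2
F4,2,6
F8,2,8
FC5,3,1
FC6,3,7
T7,4,0
T8,4,8
P7,6,0
P8,6,8
O1,8,3
O2,8,5
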