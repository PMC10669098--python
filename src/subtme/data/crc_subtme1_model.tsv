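gene	coef
DIAPH2	-0.666
TNFRSF9	-0.654
SH3BGRL3	0.735
RPS4Y1	0.138
SLC11A2	0.771
RPS4X	1.210
NDUFA11	0.987
SLC43A3	0.565
RER1	-1.506
ACTG1	-1.576
FAM3C	0.991
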