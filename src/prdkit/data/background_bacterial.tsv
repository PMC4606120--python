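residue	probability
A	0.089
C	0.012
D	0.054
E	0.061
F	0.039
G	0.072
H	0.022
I	0.060
K	0.058
L	0.099
M	0.028
N	0.039
P	0.044
Q	0.039
R	0.055
S	0.066
T	0.054
V	0.069
W	0.011
Y	0.029
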