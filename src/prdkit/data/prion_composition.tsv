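residue	probability
A	0.016875
C	0.016875
D	0.016875
E	0.016875
F	0.016875
G	0.11
H	0.016875
I	0.016875
K	0.016875
L	0.016875
M	0.016875
N	0.30
P	0.016875
Q	0.21
R	0.016875
S	0.11
T	0.016875
V	0.016875
W	0.016875
Y	0.016875
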