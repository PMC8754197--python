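amino_acid	energy
A	1.32
C	-1.45
D	-0.67
E	-0.81
F	0.76
G	0.79
H	-0.30
I	1.14
K	-0.71
L	1.05
M	0.53
N	-0.63
P	-1.62
Q	-0.54
R	-0.10
S	0.28
T	0.41
V	0.98
W	1.22
Y	0.67
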