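aa	cost
A	11.7
C	24.7
D	12.7
E	15.3
F	52.0
G	11.7
H	38.3
I	32.3
K	30.3
L	27.3
M	34.3
N	14.7
P	20.3
Q	16.3
R	27.3
S	11.7
T	18.7
V	23.3
W	74.3
Y	50.0
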