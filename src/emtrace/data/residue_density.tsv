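# Expected relative density per residue type: heavy-atom count of the
# residue (backbone N, CA, C, O plus side chain). Normalized to mean 1
# over the 20 entries when loaded. Edit or replace via config to supply
# a calibrated table.
G	4
A	5
S	6
C	6
T	7
V	7
P	7
L	8
I	8
N	8
D	8
M	8
Q	9
E	9
K	9
H	10
F	11
R	11
Y	12
W	14
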