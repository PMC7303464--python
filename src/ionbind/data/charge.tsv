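# Polarization charge classes of the 20 amino acids (editable).
# residue<TAB>class; classes: + positive, - negative, 0 uncharged.
# The padding residue X is added automatically as its own class (q = 4).
K	+
R	+
H	+
D	-
E	-
A	0
C	0
F	0
G	0
I	0
L	0
M	0
N	0
P	0
Q	0
S	0
T	0
V	0
W	0
Y	0
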