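# Hydropathy classes of the 20 amino acids (editable).
# residue<TAB>class; P, G and C form singleton classes, the rest split
# into hydrophobic (h), polar-uncharged (p) and charged (c) groups.
# The padding residue X is added automatically as its own class (q = 7).
P	P
G	G
C	C
A	h
V	h
L	h
I	h
M	h
F	h
W	h
S	p
T	p
N	p
Q	p
Y	p
H	p
D	c
E	c
K	c
R	c
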