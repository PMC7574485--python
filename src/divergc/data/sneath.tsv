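# Sneath-style dissimilarity index (construction after Sneath 1966, J Theor Biol 12:157).
# Generated by scripts/derive_matrices.py; rows = from-residue, columns = to-residue.
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	25	37.5	43.75	31.25	6.25	62.5	18.75	50	12.5	25	37.5	18.75	43.75	56.25	25	37.5	12.5	37.5	43.75
C	25	0	25	31.25	31.25	31.25	50	31.25	37.5	25	12.5	25	31.25	31.25	43.75	25	25	25	37.5	31.25
D	37.5	25	0	6.25	43.75	31.25	37.5	43.75	25	37.5	37.5	25	31.25	31.25	31.25	25	25	37.5	50	43.75
E	43.75	31.25	6.25	0	37.5	37.5	31.25	37.5	18.75	31.25	31.25	31.25	37.5	25	25	31.25	31.25	43.75	43.75	37.5
F	31.25	31.25	43.75	37.5	0	37.5	31.25	25	43.75	18.75	18.75	43.75	25	37.5	50	43.75	43.75	31.25	6.25	12.5
G	6.25	31.25	31.25	37.5	37.5	0	56.25	25	43.75	18.75	31.25	31.25	12.5	37.5	50	18.75	31.25	18.75	43.75	50
H	62.5	50	37.5	31.25	31.25	56.25	0	56.25	12.5	50	50	37.5	43.75	31.25	18.75	50	50	62.5	25	31.25
I	18.75	31.25	43.75	37.5	25	25	56.25	0	43.75	6.25	18.75	43.75	25	37.5	50	43.75	31.25	6.25	31.25	37.5
K	50	37.5	25	18.75	43.75	43.75	12.5	43.75	0	37.5	37.5	25	43.75	18.75	6.25	37.5	37.5	50	37.5	43.75
L	12.5	25	37.5	31.25	18.75	18.75	50	6.25	37.5	0	12.5	37.5	18.75	31.25	43.75	37.5	37.5	12.5	25	31.25
M	25	12.5	37.5	31.25	18.75	31.25	50	18.75	37.5	12.5	0	37.5	31.25	31.25	43.75	37.5	37.5	25	25	31.25
N	37.5	25	25	31.25	43.75	31.25	37.5	43.75	25	37.5	37.5	0	31.25	6.25	31.25	25	25	37.5	37.5	43.75
P	18.75	31.25	31.25	37.5	25	12.5	43.75	25	43.75	18.75	31.25	31.25	0	37.5	50	31.25	31.25	18.75	31.25	37.5
Q	43.75	31.25	31.25	25	37.5	37.5	31.25	37.5	18.75	31.25	31.25	6.25	37.5	0	25	31.25	31.25	43.75	31.25	37.5
R	56.25	43.75	31.25	25	50	50	18.75	50	6.25	43.75	43.75	31.25	50	25	0	43.75	43.75	56.25	43.75	50
S	25	25	25	31.25	43.75	18.75	50	43.75	37.5	37.5	37.5	25	31.25	31.25	43.75	0	12.5	37.5	50	31.25
T	37.5	25	25	31.25	43.75	31.25	50	31.25	37.5	37.5	37.5	25	31.25	31.25	43.75	12.5	0	25	50	31.25
V	12.5	25	37.5	43.75	31.25	18.75	62.5	6.25	50	12.5	25	37.5	18.75	43.75	56.25	37.5	25	0	37.5	43.75
W	37.5	37.5	50	43.75	6.25	43.75	25	31.25	37.5	25	25	37.5	31.25	31.25	43.75	50	50	37.5	0	18.75
Y	43.75	31.25	43.75	37.5	12.5	50	31.25	37.5	43.75	31.25	31.25	43.75	37.5	37.5	50	31.25	31.25	43.75	18.75	0
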