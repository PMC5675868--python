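residue	p_helix	p_strand
A	1.42	0.83
R	0.98	0.93
N	0.67	0.89
D	1.01	0.54
C	0.70	1.19
Q	1.11	1.10
E	1.51	0.37
G	0.57	0.75
H	1.00	0.87
I	1.08	1.60
L	1.21	1.30
K	1.16	0.74
M	1.45	1.05
F	1.13	1.38
P	0.57	0.55
S	0.77	0.75
T	0.83	1.19
W	1.08	1.37
Y	0.69	1.47
V	1.06	1.70
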