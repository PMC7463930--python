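aa	z1	z2	z3
A	0.07	-1.73	0.09
R	2.88	2.52	-3.44
N	3.22	1.45	0.84
D	3.64	1.13	2.36
C	0.71	-0.97	4.13
Q	2.18	0.53	-1.14
E	3.08	0.39	-0.07
G	2.23	-5.36	0.30
H	2.41	1.74	1.11
I	-4.44	-1.68	-1.03
L	-4.19	-1.03	-0.98
K	2.84	1.41	-3.14
M	-2.49	-0.27	-0.41
F	-4.92	1.30	0.45
P	-1.22	0.88	2.23
S	1.96	-1.63	0.57
T	0.92	-2.09	-1.40
W	-4.75	3.65	0.85
Y	-1.39	2.32	0.01
V	-2.69	-2.53	-1.29
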