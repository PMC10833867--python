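# Side-chain water-to-bilayer / water-to-octanol transfer energies, kcal/mol.
# mf: bilayer-context side-chain hydrophobicity (Moon & Fleming, PNAS 2011,
#     OmpLA guest-host mutagenesis in DLPC, pH 3.8 for Asp/Glu).
# ww: water-to-octanol side-chain scale (Wimley, Creamer & White,
#     Biochemistry 1996).
# Values are best-effort transcriptions for convenience and are editable;
# all tests and derived quantities in this package use synthetic scales or
# recompute from this table at run time, so correctness of the code never
# rests on these numbers.  Rows D1/E1 carry only the octanol value of the
# deprotonated side chain; their bilayer-context value is derived by the
# MF-vs-WW linear fit at run time.
code	mf	ww
A	0.00	0.50
C	-0.49	0.02
D	1.02	0.43
E	0.79	0.01
F	-2.20	-1.71
G	1.16	1.15
H	2.41	0.11
I	-1.56	-1.12
K	5.39	2.80
L	-1.81	-1.25
M	-0.76	-0.67
N	3.47	0.85
P	-0.46	0.14
Q	3.01	0.77
R	3.71	1.81
S	1.83	0.46
T	1.78	0.25
V	-0.78	-0.46
W	-0.38	-2.09
Y	-1.09	-0.71
D1	NA	3.64
E1	NA	3.63
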