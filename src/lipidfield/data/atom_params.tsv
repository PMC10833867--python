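# Per-atom parameters for the 20 canonical amino acids (heavy atoms only).
# charge: fixed partial charge in elementary charges, with hydrogen charges
#   collapsed onto their bound heavy atom (CHARMM36-like grouping; each
#   residue sums to its formal charge, Asp/Glu carry the deprotonated
#   neutral-pH form).  Override with a user table for production charges.
# ttype: water-to-bilayer transfer atom type.  COO = carboxylate carbon,
#   OOC = carboxylate oxygen (kept distinct so the neutral-pH Asp/Glu
#   augmentation can renew exactly these types).
aa	atom	ttype	charge
A	N	Nbb	-0.16
A	CA	CAbb	0.16
A	C	Cbb	0.51
A	O	Obb	-0.51
A	CB	CH3	0.00
R	N	Nbb	-0.16
R	CA	CAbb	0.16
R	C	Cbb	0.51
R	O	Obb	-0.51
R	CB	CH2	0.00
R	CG	CH2	0.00
R	CD	CH2	0.38
R	NE	Nguan	-0.26
R	CZ	Cguan	0.64
R	NH1	Nguan	0.12
R	NH2	Nguan	0.12
N	N	Nbb	-0.16
N	CA	CAbb	0.16
N	C	Cbb	0.51
N	O	Obb	-0.51
N	CB	CH2	0.00
N	CG	Camide	0.55
N	OD1	Oamide	-0.55
N	ND2	Namide	0.00
D	N	Nbb	-0.16
D	CA	CAbb	0.16
D	C	Cbb	0.51
D	O	Obb	-0.51
D	CB	CH2	-0.10
D	CG	COO	0.62
D	OD1	OOC	-0.76
D	OD2	OOC	-0.76
C	N	Nbb	-0.16
C	CA	CAbb	0.16
C	C	Cbb	0.51
C	O	Obb	-0.51
C	CB	CH2	0.07
C	SG	S	-0.07
Q	N	Nbb	-0.16
Q	CA	CAbb	0.16
Q	C	Cbb	0.51
Q	O	Obb	-0.51
Q	CB	CH2	0.00
Q	CG	CH2	0.00
Q	CD	Camide	0.55
Q	OE1	Oamide	-0.55
Q	NE2	Namide	0.00
E	N	Nbb	-0.16
E	CA	CAbb	0.16
E	C	Cbb	0.51
E	O	Obb	-0.51
E	CB	CH2	0.00
E	CG	CH2	-0.10
E	CD	COO	0.62
E	OE1	OOC	-0.76
E	OE2	OOC	-0.76
G	N	Nbb	-0.16
G	CA	CAbb	0.16
G	C	Cbb	0.51
G	O	Obb	-0.51
H	N	Nbb	-0.16
H	CA	CAbb	0.16
H	C	Cbb	0.51
H	O	Obb	-0.51
H	CB	CH2	0.00
H	CG	Caro	-0.05
H	ND1	Nhis	-0.04
H	CD2	Caro	0.10
H	CE1	Caro	0.34
H	NE2	Nhis	-0.35
I	N	Nbb	-0.16
I	CA	CAbb	0.16
I	C	Cbb	0.51
I	O	Obb	-0.51
I	CB	CH1	0.00
I	CG1	CH2	0.00
I	CG2	CH3	0.00
I	CD1	CH3	0.00
L	N	Nbb	-0.16
L	CA	CAbb	0.16
L	C	Cbb	0.51
L	O	Obb	-0.51
L	CB	CH2	0.00
L	CG	CH1	0.00
L	CD1	CH3	0.00
L	CD2	CH3	0.00
K	N	Nbb	-0.16
K	CA	CAbb	0.16
K	C	Cbb	0.51
K	O	Obb	-0.51
K	CB	CH2	0.00
K	CG	CH2	0.00
K	CD	CH2	0.00
K	CE	CH2	0.31
K	NZ	Nlys	0.69
M	N	Nbb	-0.16
M	CA	CAbb	0.16
M	C	Cbb	0.51
M	O	Obb	-0.51
M	CB	CH2	0.00
M	CG	CH2	0.04
M	SD	S	-0.09
M	CE	CH3	0.05
F	N	Nbb	-0.16
F	CA	CAbb	0.16
F	C	Cbb	0.51
F	O	Obb	-0.51
F	CB	CH2	0.00
F	CG	Caro	0.00
F	CD1	Caro	0.00
F	CD2	Caro	0.00
F	CE1	Caro	0.00
F	CE2	Caro	0.00
F	CZ	Caro	0.00
P	N	Nbb	-0.16
P	CA	CAbb	0.16
P	C	Cbb	0.51
P	O	Obb	-0.51
P	CB	CH2	0.00
P	CG	CH2	0.00
P	CD	CH2	0.00
S	N	Nbb	-0.16
S	CA	CAbb	0.16
S	C	Cbb	0.51
S	O	Obb	-0.51
S	CB	CH2	0.23
S	OG	OH	-0.23
T	N	Nbb	-0.16
T	CA	CAbb	0.16
T	C	Cbb	0.51
T	O	Obb	-0.51
T	CB	CH1	0.23
T	OG1	OH	-0.23
T	CG2	CH3	0.00
W	N	Nbb	-0.16
W	CA	CAbb	0.16
W	C	Cbb	0.51
W	O	Obb	-0.51
W	CB	CH2	0.00
W	CG	Caro	-0.03
W	CD1	Caro	0.15
W	NE1	Naro	-0.23
W	CE2	Caro	0.13
W	CD2	Caro	-0.02
W	CE3	Caro	0.00
W	CZ2	Caro	0.00
W	CZ3	Caro	0.00
W	CH2	Caro	0.00
Y	N	Nbb	-0.16
Y	CA	CAbb	0.16
Y	C	Cbb	0.51
Y	O	Obb	-0.51
Y	CB	CH2	0.00
Y	CG	Caro	0.00
Y	CD1	Caro	0.00
Y	CD2	Caro	0.00
Y	CE1	Caro	0.00
Y	CE2	Caro	0.00
Y	CZ	Caro	0.11
Y	OH	OH	-0.11
V	N	Nbb	-0.16
V	CA	CAbb	0.16
V	C	Cbb	0.51
V	O	Obb	-0.51
V	CB	CH1	0.00
V	CG1	CH3	0.00
V	CG2	CH3	0.00
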