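# multipk heavy-atom parameter set: united-hydrogen partial charges (e) and cavity radii (A)
# 'neutral' is the reference protonation variant; NTER/CTER rows patch the terminal backbone group
residue	variant	atom	charge	radius
ALA	neutral	N	-0.1600	1.55
ALA	neutral	CA	0.1600	2.00
ALA	neutral	C	0.5100	1.70
ALA	neutral	O	-0.5100	1.50
ALA	neutral	CB	0.0000	2.00
GLY	neutral	N	-0.1600	1.55
GLY	neutral	CA	0.1600	2.00
GLY	neutral	C	0.5100	1.70
GLY	neutral	O	-0.5100	1.50
SER	neutral	N	-0.1600	1.55
SER	neutral	CA	0.1600	2.00
SER	neutral	C	0.5100	1.70
SER	neutral	O	-0.5100	1.50
SER	neutral	CB	0.2500	2.00
SER	neutral	OG	-0.2500	1.50
THR	neutral	N	-0.1600	1.55
THR	neutral	CA	0.1600	2.00
THR	neutral	C	0.5100	1.70
THR	neutral	O	-0.5100	1.50
THR	neutral	CB	0.2500	2.00
THR	neutral	OG1	-0.2500	1.50
THR	neutral	CG2	0.0000	2.00
CYS	neutral	N	-0.1600	1.55
CYS	neutral	CA	0.1600	2.00
CYS	neutral	C	0.5100	1.70
CYS	neutral	O	-0.5100	1.50
CYS	neutral	CB	0.1100	2.00
CYS	neutral	SG	-0.1100	1.85
VAL	neutral	N	-0.1600	1.55
VAL	neutral	CA	0.1600	2.00
VAL	neutral	C	0.5100	1.70
VAL	neutral	O	-0.5100	1.50
VAL	neutral	CB	0.0000	2.00
VAL	neutral	CG1	0.0000	2.00
VAL	neutral	CG2	0.0000	2.00
LEU	neutral	N	-0.1600	1.55
LEU	neutral	CA	0.1600	2.00
LEU	neutral	C	0.5100	1.70
LEU	neutral	O	-0.5100	1.50
LEU	neutral	CB	0.0000	2.00
LEU	neutral	CG	0.0000	2.00
LEU	neutral	CD1	0.0000	2.00
LEU	neutral	CD2	0.0000	2.00
ILE	neutral	N	-0.1600	1.55
ILE	neutral	CA	0.1600	2.00
ILE	neutral	C	0.5100	1.70
ILE	neutral	O	-0.5100	1.50
ILE	neutral	CB	0.0000	2.00
ILE	neutral	CG1	0.0000	2.00
ILE	neutral	CG2	0.0000	2.00
ILE	neutral	CD1	0.0000	2.00
PRO	neutral	N	-0.1600	1.55
PRO	neutral	CA	0.1600	2.00
PRO	neutral	C	0.5100	1.70
PRO	neutral	O	-0.5100	1.50
PRO	neutral	CB	0.0000	2.00
PRO	neutral	CG	0.0000	2.00
PRO	neutral	CD	0.0000	2.00
MET	neutral	N	-0.1600	1.55
MET	neutral	CA	0.1600	2.00
MET	neutral	C	0.5100	1.70
MET	neutral	O	-0.5100	1.50
MET	neutral	CB	0.0000	2.00
MET	neutral	CG	0.0400	2.00
MET	neutral	SD	-0.0900	1.85
MET	neutral	CE	0.0500	2.00
PHE	neutral	N	-0.1600	1.55
PHE	neutral	CA	0.1600	2.00
PHE	neutral	C	0.5100	1.70
PHE	neutral	O	-0.5100	1.50
PHE	neutral	CB	0.0000	2.00
PHE	neutral	CG	0.0000	1.70
PHE	neutral	CD1	0.0000	1.70
PHE	neutral	CD2	0.0000	1.70
PHE	neutral	CE1	0.0000	1.70
PHE	neutral	CE2	0.0000	1.70
PHE	neutral	CZ	0.0000	1.70
TRP	neutral	N	-0.1600	1.55
TRP	neutral	CA	0.1600	2.00
TRP	neutral	C	0.5100	1.70
TRP	neutral	O	-0.5100	1.50
TRP	neutral	CB	0.0000	2.00
TRP	neutral	CG	0.0000	1.70
TRP	neutral	CD1	0.1500	1.70
TRP	neutral	CD2	0.0000	1.70
TRP	neutral	NE1	-0.3000	1.55
TRP	neutral	CE2	0.1500	1.70
TRP	neutral	CE3	0.0000	1.70
TRP	neutral	CZ2	0.0000	1.70
TRP	neutral	CZ3	0.0000	1.70
TRP	neutral	CH2	0.0000	1.70
ASN	neutral	N	-0.1600	1.55
ASN	neutral	CA	0.1600	2.00
ASN	neutral	C	0.5100	1.70
ASN	neutral	O	-0.5100	1.50
ASN	neutral	CB	0.0000	2.00
ASN	neutral	CG	0.5500	1.70
ASN	neutral	OD1	-0.5500	1.50
ASN	neutral	ND2	0.0000	1.55
GLN	neutral	N	-0.1600	1.55
GLN	neutral	CA	0.1600	2.00
GLN	neutral	C	0.5100	1.70
GLN	neutral	O	-0.5100	1.50
GLN	neutral	CB	0.0000	2.00
GLN	neutral	CG	0.0000	2.00
GLN	neutral	CD	0.5500	1.70
GLN	neutral	OE1	-0.5500	1.50
GLN	neutral	NE2	0.0000	1.55
GLU	neutral	N	-0.1600	1.55
GLU	neutral	CA	0.1600	2.00
GLU	neutral	C	0.5100	1.70
GLU	neutral	O	-0.5100	1.50
GLU	neutral	CB	0.0000	2.00
GLU	neutral	CG	0.0000	2.00
GLU	neutral	CD	0.6000	1.70
GLU	neutral	OE1	-0.4300	1.50
GLU	neutral	OE2	-0.1700	1.50
GLU	charged	N	-0.1600	1.55
GLU	charged	CA	0.1600	2.00
GLU	charged	C	0.5100	1.70
GLU	charged	O	-0.5100	1.50
GLU	charged	CB	0.0000	2.00
GLU	charged	CG	-0.1000	2.00
GLU	charged	CD	0.6200	1.70
GLU	charged	OE1	-0.7600	1.50
GLU	charged	OE2	-0.7600	1.50
ASP	neutral	N	-0.1600	1.55
ASP	neutral	CA	0.1600	2.00
ASP	neutral	C	0.5100	1.70
ASP	neutral	O	-0.5100	1.50
ASP	neutral	CB	0.0000	2.00
ASP	neutral	CG	0.6000	1.70
ASP	neutral	OD1	-0.4300	1.50
ASP	neutral	OD2	-0.1700	1.50
ASP	charged	N	-0.1600	1.55
ASP	charged	CA	0.1600	2.00
ASP	charged	C	0.5100	1.70
ASP	charged	O	-0.5100	1.50
ASP	charged	CB	-0.1000	2.00
ASP	charged	CG	0.6200	1.70
ASP	charged	OD1	-0.7600	1.50
ASP	charged	OD2	-0.7600	1.50
LYS	neutral	N	-0.1600	1.55
LYS	neutral	CA	0.1600	2.00
LYS	neutral	C	0.5100	1.70
LYS	neutral	O	-0.5100	1.50
LYS	neutral	CB	0.0000	2.00
LYS	neutral	CG	0.0000	2.00
LYS	neutral	CD	0.0000	2.00
LYS	neutral	CE	0.1500	2.00
LYS	neutral	NZ	-0.1500	1.55
LYS	charged	N	-0.1600	1.55
LYS	charged	CA	0.1600	2.00
LYS	charged	C	0.5100	1.70
LYS	charged	O	-0.5100	1.50
LYS	charged	CB	0.0000	2.00
LYS	charged	CG	0.0000	2.00
LYS	charged	CD	0.0000	2.00
LYS	charged	CE	0.2500	2.00
LYS	charged	NZ	0.7500	1.55
ARG	neutral	N	-0.1600	1.55
ARG	neutral	CA	0.1600	2.00
ARG	neutral	C	0.5100	1.70
ARG	neutral	O	-0.5100	1.50
ARG	neutral	CB	0.0000	2.00
ARG	neutral	CG	0.0000	2.00
ARG	neutral	CD	0.0000	2.00
ARG	neutral	NE	-0.3000	1.55
ARG	neutral	CZ	0.6000	1.70
ARG	neutral	NH1	-0.1500	1.55
ARG	neutral	NH2	-0.1500	1.55
ARG	charged	N	-0.1600	1.55
ARG	charged	CA	0.1600	2.00
ARG	charged	C	0.5100	1.70
ARG	charged	O	-0.5100	1.50
ARG	charged	CB	0.0000	2.00
ARG	charged	CG	0.0000	2.00
ARG	charged	CD	0.0000	2.00
ARG	charged	NE	-0.1000	1.55
ARG	charged	CZ	0.5000	1.70
ARG	charged	NH1	0.3000	1.55
ARG	charged	NH2	0.3000	1.55
TYR	neutral	N	-0.1600	1.55
TYR	neutral	CA	0.1600	2.00
TYR	neutral	C	0.5100	1.70
TYR	neutral	O	-0.5100	1.50
TYR	neutral	CB	0.0000	2.00
TYR	neutral	CG	0.0000	1.70
TYR	neutral	CD1	0.0000	1.70
TYR	neutral	CD2	0.0000	1.70
TYR	neutral	CE1	0.0000	1.70
TYR	neutral	CE2	0.0000	1.70
TYR	neutral	CZ	0.2500	1.70
TYR	neutral	OH	-0.2500	1.50
TYR	charged	N	-0.1600	1.55
TYR	charged	CA	0.1600	2.00
TYR	charged	C	0.5100	1.70
TYR	charged	O	-0.5100	1.50
TYR	charged	CB	0.0000	2.00
TYR	charged	CG	0.0000	1.70
TYR	charged	CD1	0.0000	1.70
TYR	charged	CD2	0.0000	1.70
TYR	charged	CE1	-0.1000	1.70
TYR	charged	CE2	-0.1000	1.70
TYR	charged	CZ	0.1000	1.70
TYR	charged	OH	-0.9000	1.50
HIS	neutral	N	-0.1600	1.55
HIS	neutral	CA	0.1600	2.00
HIS	neutral	C	0.5100	1.70
HIS	neutral	O	-0.5100	1.50
HIS	neutral	CB	0.0000	2.00
HIS	neutral	CG	0.1000	1.70
HIS	neutral	ND1	-0.4000	1.55
HIS	neutral	CD2	0.1500	1.70
HIS	neutral	CE1	0.2500	1.70
HIS	neutral	NE2	-0.1000	1.55
HIS	neutral_nd1	N	-0.1600	1.55
HIS	neutral_nd1	CA	0.1600	2.00
HIS	neutral_nd1	C	0.5100	1.70
HIS	neutral_nd1	O	-0.5100	1.50
HIS	neutral_nd1	CB	0.0000	2.00
HIS	neutral_nd1	CG	0.1000	1.70
HIS	neutral_nd1	ND1	-0.1000	1.55
HIS	neutral_nd1	CD2	0.1500	1.70
HIS	neutral_nd1	CE1	0.2500	1.70
HIS	neutral_nd1	NE2	-0.4000	1.55
HIS	charged	N	-0.1600	1.55
HIS	charged	CA	0.1600	2.00
HIS	charged	C	0.5100	1.70
HIS	charged	O	-0.5100	1.50
HIS	charged	CB	0.0000	2.00
HIS	charged	CG	0.2000	1.70
HIS	charged	ND1	0.1500	1.55
HIS	charged	CD2	0.2000	1.70
HIS	charged	CE1	0.3000	1.70
HIS	charged	NE2	0.1500	1.55
NTER	neutral	N	-0.3000	1.55
NTER	neutral	CA	0.3000	2.00
NTER	charged	N	0.6600	1.55
NTER	charged	CA	0.3400	2.00
CTER	neutral	C	0.6000	1.70
CTER	neutral	O	-0.4300	1.50
CTER	neutral	OXT	-0.1700	1.50
CTER	charged	C	0.3400	1.70
CTER	charged	O	-0.6700	1.50
CTER	charged	OXT	-0.6700	1.50
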