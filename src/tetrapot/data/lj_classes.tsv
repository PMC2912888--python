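# Mapping (residue type, atom name) -> Lennard-Jones atom class.
# "*" in the residue column matches every standard residue (backbone atoms).
# 20 classes, chemically grouped; edit or replace via assign_lj_classes(class_table=...).
# residue	atom	class
*	N	N_BB
*	CA	C_ALPHA
*	C	C_CARBONYL_BB
*	O	O_CARBONYL_BB
*	OXT	O_CARBONYL_BB
ALA	CB	C_CH3
VAL	CG1	C_CH3
VAL	CG2	C_CH3
LEU	CD1	C_CH3
LEU	CD2	C_CH3
ILE	CG2	C_CH3
ILE	CD1	C_CH3
THR	CG2	C_CH3
MET	CE	C_CH3
ARG	CB	C_CH2
ARG	CG	C_CH2
ARG	CD	C_CH2
ASN	CB	C_CH2
ASP	CB	C_CH2
CYS	CB	C_CH2
GLN	CB	C_CH2
GLN	CG	C_CH2
GLU	CB	C_CH2
GLU	CG	C_CH2
HIS	CB	C_CH2
ILE	CG1	C_CH2
LEU	CB	C_CH2
LYS	CB	C_CH2
LYS	CG	C_CH2
LYS	CD	C_CH2
LYS	CE	C_CH2
MET	CB	C_CH2
MET	CG	C_CH2
PHE	CB	C_CH2
PRO	CB	C_CH2
PRO	CG	C_CH2
PRO	CD	C_CH2
SER	CB	C_CH2
TRP	CB	C_CH2
TYR	CB	C_CH2
VAL	CB	C_CH1
LEU	CG	C_CH1
ILE	CB	C_CH1
THR	CB	C_CH1
PHE	CG	C_AROMATIC
PHE	CD1	C_AROMATIC
PHE	CD2	C_AROMATIC
PHE	CE1	C_AROMATIC
PHE	CE2	C_AROMATIC
PHE	CZ	C_AROMATIC
TYR	CG	C_AROMATIC
TYR	CD1	C_AROMATIC
TYR	CD2	C_AROMATIC
TYR	CE1	C_AROMATIC
TYR	CE2	C_AROMATIC
TYR	CZ	C_AROMATIC
TRP	CG	C_AROMATIC
TRP	CD2	C_AROMATIC
TRP	CE3	C_AROMATIC
TRP	CZ2	C_AROMATIC
TRP	CZ3	C_AROMATIC
TRP	CH2	C_AROMATIC
HIS	CG	C_RING_N
HIS	CD2	C_RING_N
HIS	CE1	C_RING_N
TRP	CD1	C_RING_N
TRP	CE2	C_RING_N
ASN	CG	C_AMIDE
GLN	CD	C_AMIDE
ASP	CG	C_CARBOXYL
GLU	CD	C_CARBOXYL
ARG	CZ	C_GUANIDINIUM
ASN	OD1	O_AMIDE
GLN	OE1	O_AMIDE
ASP	OD1	O_CARBOXYL
ASP	OD2	O_CARBOXYL
GLU	OE1	O_CARBOXYL
GLU	OE2	O_CARBOXYL
SER	OG	O_HYDROXYL
THR	OG1	O_HYDROXYL
TYR	OH	O_HYDROXYL
ASN	ND2	N_AMIDE
GLN	NE2	N_AMIDE
LYS	NZ	N_AMINE
ARG	NE	N_GUANIDINIUM
ARG	NH1	N_GUANIDINIUM
ARG	NH2	N_GUANIDINIUM
HIS	ND1	N_RING
HIS	NE2	N_RING
TRP	NE1	N_RING
CYS	SG	S_THIOETHER
MET	SD	S_THIOETHER
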