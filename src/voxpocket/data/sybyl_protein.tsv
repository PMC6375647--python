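# SYBYL atom types for heavy atoms of the 20 standard amino acids.
# Columns: residue_name <TAB> atom_name <TAB> sybyl_type
# '*' as residue_name matches any residue (backbone atoms).
*	N	N.am
*	CA	C.3
*	C	C.2
*	O	O.2
*	OXT	O.co2
ALA	CB	C.3
ARG	CB	C.3
ARG	CG	C.3
ARG	CD	C.3
ARG	NE	N.pl3
ARG	CZ	C.2
ARG	NH1	N.pl3
ARG	NH2	N.pl3
ASN	CB	C.3
ASN	CG	C.2
ASN	OD1	O.2
ASN	ND2	N.am
ASP	CB	C.3
ASP	CG	C.2
ASP	OD1	O.co2
ASP	OD2	O.co2
CYS	CB	C.3
CYS	SG	S.3
GLN	CB	C.3
GLN	CG	C.3
GLN	CD	C.2
GLN	OE1	O.2
GLN	NE2	N.am
GLU	CB	C.3
GLU	CG	C.3
GLU	CD	C.2
GLU	OE1	O.co2
GLU	OE2	O.co2
HIS	CB	C.3
HIS	CG	C.ar
HIS	ND1	N.ar
HIS	CD2	C.ar
HIS	CE1	C.ar
HIS	NE2	N.ar
ILE	CB	C.3
ILE	CG1	C.3
ILE	CG2	C.3
ILE	CD1	C.3
LEU	CB	C.3
LEU	CG	C.3
LEU	CD1	C.3
LEU	CD2	C.3
LYS	CB	C.3
LYS	CG	C.3
LYS	CD	C.3
LYS	CE	C.3
LYS	NZ	N.4
MET	CB	C.3
MET	CG	C.3
MET	SD	S.3
MET	CE	C.3
PHE	CB	C.3
PHE	CG	C.ar
PHE	CD1	C.ar
PHE	CD2	C.ar
PHE	CE1	C.ar
PHE	CE2	C.ar
PHE	CZ	C.ar
PRO	CB	C.3
PRO	CG	C.3
PRO	CD	C.3
SER	CB	C.3
SER	OG	O.3
THR	CB	C.3
THR	OG1	O.3
THR	CG2	C.3
TRP	CB	C.3
TRP	CG	C.ar
TRP	CD1	C.ar
TRP	CD2	C.ar
TRP	NE1	N.ar
TRP	CE2	C.ar
TRP	CE3	C.ar
TRP	CZ2	C.ar
TRP	CZ3	C.ar
TRP	CH2	C.ar
TYR	CB	C.3
TYR	CG	C.ar
TYR	CD1	C.ar
TYR	CD2	C.ar
TYR	CE1	C.ar
TYR	CE2	C.ar
TYR	CZ	C.ar
TYR	OH	O.3
VAL	CB	C.3
VAL	CG1	C.3
VAL	CG2	C.3
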