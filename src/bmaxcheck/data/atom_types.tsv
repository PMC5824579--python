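type_id	res_name	atom_name
1	ANY	CA
2	ANY	C
3	ILE	CB
3	THR	CB
3	VAL	CB
3	LEU	CG
4	ARG	CG
4	GLN	CG
4	LYS	CG
4	MET	CG
4	PRO	CG
4	ILE	CG1
4	LYS	CD
4	PRO	CD
5	ARG	CB
5	ASN	CB
5	ASP	CB
5	CYS	CB
5	GLN	CB
5	GLU	CB
5	HIS	CB
5	LEU	CB
5	LYS	CB
5	MET	CB
5	PHE	CB
5	PRO	CB
5	SER	CB
5	TRP	CB
5	TYR	CB
6	ARG	CD
6	GLU	CG
6	LYS	CE
7	ALA	CB
7	VAL	CG1
7	ILE	CG2
7	THR	CG2
7	VAL	CG2
7	ILE	CD1
7	LEU	CD1
7	LEU	CD2
7	MET	CE
8	PHE	CD1
8	TRP	CD1
8	TYR	CD1
8	PHE	CD2
8	TYR	CD2
8	PHE	CE1
8	TYR	CE1
8	PHE	CE2
8	TYR	CE2
8	PHE	CZ
8	TRP	CE3
8	TRP	CZ2
8	TRP	CZ3
8	TRP	CH2
9	ARG	CZ
9	TYR	CZ
9	HIS	CG
9	PHE	CG
9	TRP	CG
9	TYR	CG
9	TRP	CD2
9	TRP	CE2
10	HIS	CD2
10	HIS	CE1
11	ASN	CG
11	GLN	CD
12	ASP	CG
12	GLU	CD
13	CYS	SG
14	MET	SD
15	ANY	N
16	TRP	NE1
17	HIS	ND1
17	HIS	NE2
18	ASN	ND2
18	GLN	NE2
19	ARG	NE
19	ARG	NH1
19	ARG	NH2
20	LYS	NZ
21	ANY	O
22	ASN	OD1
22	GLN	OE1
23	ASP	OD1
23	ASP	OD2
23	GLU	OE1
23	GLU	OE2
24	SER	OG
24	THR	OG1
24	TYR	OH
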