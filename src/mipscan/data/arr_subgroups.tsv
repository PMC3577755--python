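subfamily	subgroup	h2	h5	le1	le2	note
PIP	I	F	H	T	R	AQP1-like with Thr at LE1
TIP	IA	H	I	A	V	Group I: conserved His/Ile, Val at LE2
TIP	IB	H	V	A	V	LE2 Val inferred from the Group I description; H5 Val
TIP	IIA	H	I	G	R	Gly at LE1, conserved Arg at LE2
TIP	IIB	H	I	A	R	Ala at LE1, Arg at LE2
TIP	IIC	H	I	A	L	Leu at LE2
TIP	III	S	V	G	C	Ser replaces His at H2; Cys at LE2
NIP	I	W	V	A	R	nodulin-26 tetrad
NIP	IIA	A	I	G	R	AtNIP5;1-like (AIGR)
NIP	IIB	A	V	G	R	Ala for Trp at H2, Gly for Ala at LE1
NIP	III	G	S	G	R	OsLsi1-like (GSGR)
NIP	IVA	N	V	S	R	reconstructed from prose: Asn at H2 and Ser at LE1
NIP	IVB	T	V	G	R	reconstructed from prose: Thr replaces Ala at H2
SIP	I	I	T	P	F	Ile/Thr/Pro/Phe
SIP	II	V	M	P	N	Val/Met/Pro/Asn
SIP	III	N	I	P	N	Asn/Ile replace Val/Met of Group II
XIP	I	V	I	V	R	VIVR
XIP	I	V	I	A	R	Ala replaces Val at LE1 in the second isoform
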