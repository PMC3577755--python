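name	terminus	pattern	acceptor_index	note
RKXSXXR/K	N	RKX.XX(R/K)	4	conserved Ser in PIPs; Thr/Pro/His/Arg replacements in other subfamilies
KXSXXR/K	N	KX.XX(R/K)	3	short form of the N-terminal motif
SFRS	C	SFRS	1	PIP2-type C-terminal motif
PFK/ST/S	C	PF(K/S)(T/S)	4	PIP1-type C-terminal motif (Pro replaces the AQP-type Ser)
KXXSXXK	C	KXX.XXK	4	NIP1-type C-terminal motif (incl. the nodulin-26 site)
KSXXR	C	K.XXR	2	NIP2-type C-terminal motif
KIFKT	C	KIFK.	5	NIP4-type C-terminal motif
XSFRR	C	X.FRR	2	NIP5/NIP6-type C-terminal motif
XPFCS	C	XPFC.	5	NIP7-type C-terminal motif
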