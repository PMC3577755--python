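gene_name	locus_name	genome_location	est	ntm	pl	rse	psl	kaks	comment
GmPIP1;1	Glyma03g14150	18018230..18021565	Yes	6	285	15	PLAS	<1
GmPIP1;2	Glyma18g42630	51879812..51881980	Yes	6	305	23	PLAS	?
GmPIP1;3	Glyma01g42950	54066066..54068057	Yes	6	287	51	PLAS	<1
GmPIP1;4	Glyma11g02530	1656129..1658174	Yes	6	287	63	PLAS	<1
GmPIP1;5	Glyma05g37730	41267148..41268807	Yes	6	288	296	PLAS	<1
GmPIP1;6	Glyma08g01860	1202356..1204135	Yes	6	290	82	PLAS	<1
GmPIP1;7	Glyma14g06680	4894197..4896207	Yes	6	290	1635	PLAS	<1
GmPIP1;8	Glyma11g35030	36767510..36769078	Yes	6	290	1169	PLAS	<1
GmPIP2;1	Glyma04g00450	227991..229365	Yes	6	276	96	PLAS	<1
GmPIP2;2	Glyma06g00550	264336..265850	Yes	6	279	16	PLAS	<1
GmPIP2;3	Glyma11g20600	17405538..17407774	Yes	6	287	300	PLAS	<1
GmPIP2;4	Glyma12g08040	5736134..5738571	Yes	6	287	531	PLAS	<1
GmPIP2;5	Glyma12g29510	32929324..32931027	Yes	6	288	324	PLAS	<1
GmPIP2;6	Glyma13g40100	40664607..40666361	Yes	6	288	1008	PLAS	<1
GmPIP2;7	Glyma03g33800	41279731..41281496	Yes	6	287	1	PLAS	<1
GmPIP2;8	Glyma19g36530	43803906..43806142	Yes	6	286	1	PLAS	<1
GmPIP2;9	Glyma02g08110	6345032..6348612	Yes	6	286	5	PLAS	<1
GmPIP2;10	Glyma16g27130	31144909..31148555	Yes	6	286	39	PLAS	<1
GmPIP2;11	Glyma16g27140	31154978..31156159	Yes	6	286	62	PLAS	<1
GmPIP2;12	Glyma02g08120	6358474..6361413	Yes	6	286	1	PLAS	<1
GmPIP2;13	Glyma10g35520	43763682..43766888	Yes	6	297	159	PLAS	<1
GmPIP2;14	Glyma20g32000	40621201..40624089	Yes	6	285	106	PLAS	<1
PseudoPIP#1	Glyma01g27970	37458238..37460664	?	5	254	0		<1	Not full length
PseudoPIP#2	Glyma02g42220	47295297..47297674	Yes	5	317	1082		1	2nd NPA missing, Not full length
PseudoPIP#3	Glyma14g24430	29321210..29322268	?	4	188	0		>1	NPA modified
PseudoPIP#4	Glyma18g03330	2228741..2229353	Yes	3	128	2		?	1st NPA missing, Not full length
GmTIP1;1	Glyma02g10520	8409966..8411440	Yes	6	253	0	CYTO	<1
GmTIP1;2	Glyma18g52360	60989768..60991401	?	6	253	0	CYTO	<1
GmTIP1;3	Glyma10g43680	50271428..50272965	?	7	253	0	PLAS	<1
GmTIP1;4	Glyma11g15200	10892421..10894109	Yes	6	253	17	PLAS	<1
GmTIP1;5	Glyma12g07120	4870480..4871652	?	6	246	0	PLAS	<1
GmTIP1;6	Glyma13g40820	41270585..41271998	Yes	7	253	24	VACU	<1
GmTIP1;7	Glyma03g34310	41779243..41780564	Yes	6	251	2244	CYTO	<1
GmTIP1;8	Glyma19g37000	44258426..44259853	Yes	6	251	1181	CYTO	<1
GmTIP1;9	Glyma13g20940	24436182..24438466	Yes	6	251	21	ER	<1
GmTIP2;1	Glyma01g41670	53110677..53113455	Yes	6	250	693	PLAS	<1
GmTIP2;2	Glyma11g03690	2476012..2478825	Yes	6	250	903	PLAS	<1
GmTIP2;3	Glyma07g02060	1435523..1437651	Yes	6	249	14	VACU	<1
GmTIP2;4	Glyma08g21730	16535219..16537122	Yes	6	249	15	VACU	<1
GmTIP2;5	Glyma13g43250	43018922..43020336	Yes	6	248	1	PLAS	<1
GmTIP2;6	Glyma15g02090	1393557..1395809	Yes	6	248	0	CYTO	<1
GmTIP2;7	Glyma19g04450	4625496..4626575	?	6	238	0	PLAS	<1
GmTIP3;1	Glyma09g28930	35913523..35915582	Yes	6	256	0	CYTO	<1
GmTIP3;2	Glyma16g33530	36421819..36424304	Yes	6	256	0	MITO	<1
GmTIP3;3	Glyma10g31750	40238530..40240337	Yes	6	255	0	CYTO	<1
GmTIP3;4	Glyma20g35860	44068541..44070258	?	6	255	0	CYTO	<1
GmTIP4;1	Glyma04g08830	6943153..6944783	Yes	6	247	357	VACU	<1
GmTIP4;2	Glyma06g08910	6498818..6500103	Yes	6	247	89	CYTO	<1
GmTIP5;1	Glyma09g35860	41742635..41743884	?	6	248	0	CHLO	<1
PseudoTIP#1	Glyma15g04630	3223182..3223750	?	5	153	0			2nd NPA missing
PseudoTIP#2	Glyma10g06750	5471639..5473323	?	5	189	0			2nd NPA missing
PseudoTIP#3	Glyma12g01490	895186..897034	?	5	188	0		<1	Not full length
GmNIP1;1	Glyma05g29510	35105884..35108185	Yes	6	271	2	VACU
GmNIP1;2	Glyma08g12660	9268559..9270946	Yes	6	275	1	PLAS
GmNIP1;3	Glyma13g29690	32551102..32553703	Yes	6	274	0	PLAS	<1
GmNIP1;4	Glyma15g09370	6704209..6706791	Yes	6	268	0	PLAS	<1
GmNIP1;5Nod26	Glyma08g12650	9262302..9265834	Yes	6	272	0	PLAS
GmNIP2;1	Glyma09g37280	42824943..42829709	Yes	6	294	279	PLAS
GmNIP2;2	Glyma18g49410	58816436..58821548	Yes	6	296	124	EXTR
GmNIP4;1	Glyma07g34150	39062920..39065820	?	6	269	0	VACU	<1
GmNIP5;1	Glyma10g36560	44670892..44676555	Yes	6	291	38	PLAS
GmNIP6;1	Glyma08g23230	17701761..17706495	Yes	6	307	1	PLAS	<1
GmNIP6;2	Glyma15g00620	355676..359967	Yes	6	305	15	PLAS	<1
GmNIP7;1	Glyma02g15870	14348789..14351092	?	6	294	0	PLAS	?
GmNIP7;2	Glyma10g03870	2898450..2900795	?	6	277	0	PLAS
PseudoNIP#1	Glyma02g41400	46541265..46543675	?	7	216	0		<1	Not full length
PseudoNIP#2	Glyma05g29500	35100591..35104790	Yes	5	244	0			TM5 missing, but rest similar to GmNIP1;1
PseudoNIP#3	Glyma07g02760	1873672..1881683	?	5	182	0			Not full length
PseudoNIP#4	Glyma07g02800	1909545..1912431	Yes	4	185	0			Not full length
PseudoNIP#5	Glyma07g03030	2087864..2090380	?	4	249	0			Not full length
PseudoNIP#6	Glyma13g01800	1483837..1490592	?	5	227	0			1st NPA missing, Not full length
PseudoNIP#7	Glyma14g07560	5711153..5714115	?	7	217	0		<1	Not full length
PseudoNIP#8	Glyma14g35030	43721841..43723560	?	7	220	0			Not full length
PseudoNIP#9	Glyma20g01750	1269856..1275738	?	6	239	0			1st NPA missing, Not full length
PseudoNIP#10	Glyma20g31040	39698455..39705450	?	5	264	42			Not full length
PseudoNIP#11	Glyma08g29500	23981039..23981867	?	2	92	0			2nd NPA missing, Not full length
PseudoNIP#12	Glyma14g13260	12544663..12544842	?	2	60	0			1st NPA missing
GmSIP1;1	Glyma02g07680	6061309..6065568	Yes	6	248	1	VACU	<1
GmSIP1;2	Glyma16g26720	30813218..30817735	?	6	246	1	VACU	<1
GmSIP1;3	Glyma19g28430	35912781..35923174	Yes	6	249	27	PLAS	<1
GmSIP1;4	Glyma16g04800	4096288..4102424	Yes	6	249	23	PLAS
GmSIP1;5	Glyma12g10430	8369034..8369846	Yes	6	240	0	PLAS	<1
GmSIP1;6	Glyma06g46340	48987251..48988278	Yes	6	240	1	PLAS
PseudoSIP#1	Glyma01g04520	4099619..4100401	?	2	141	0		>1	2nd NPA missing, Not full length
PseudoSIP#2	Glyma03g27340	35075328..35078322	Yes	5	231	5		<1	Not full length
PseudoSIP#3	Glyma19g30320	37949307..37951724	Yes	5	237	10		<1	Not full length
GmXIP1;1	Glyma11g10360	7439903..7440754	?	6	271	0	EXTR	<1
GmXIP1;2	Glyma12g02640	1729006..1730580	Yes	6	313	0	CYTO
PseudoXIP#1	Glyma11g10350	7436965..7438428	?	5	202	23			Not full length
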