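substrate	slot	region	filter
ammonia	sdp1_4	loopC	Fxx(K/N)xxxFxxT
ammonia	sdp5	loopE	A
ammonia	sdp6_9	cterm	DxxLxExT
boric_acid	sdp1_4	tm2_loopB	TxxIxxxHxxP
boric_acid	sdp5	tm4	E
boric_acid	sdp6_9	tm5	LxxLxT/AxP
co2	sdp1_4	tm3	L/V/IxxIxxxCxxA
co2	sdp5	loopD	I
co2	sdp6_9	loopE_tm6	DxxWxDxW
h2o2	sdp1_4	tm3	A/SxxA/GxxxL/VxxA/F/L/V
h2o2	sdp5	tm5	I/V
h2o2	sdp6_9	loopE_tm6	H/I/L/QxxF/YxA/VxP
urea	sdp1_4	loopB	HxxPxxxF/I/LxxA/F
urea	sdp5	tm4	L
urea	sdp6_9	tm5_loopE	A/PxxG/SxG/SxN
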