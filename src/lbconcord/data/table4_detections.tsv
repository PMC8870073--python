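patient_id	gene	aa_change	in_tumor	in_ev	in_cf
1	IDH2	R261H	1	1	1
1	IDH2	R131H	1	1	1
1	IDH2	R209H	1	1	1
1	RAD51B	T107K	1	0	0
1	TP53	Y220N	1	0	0
1	TP53	Y127N	1	0	0
1	TP53	Y88N	1	0	0
2	BRCA2	E394A	0	1	1
2	BRIP1	P47A	0	1	1
3	BRAF	L319I	0	1	0
3	TP53	R141H	1	1	1
4	ATM	E2156D	1	0	0
4	BRAF	L319I	0	1	0
4	PTEN	Y155C	1	1	1
4	ROS1	G374A	1	1	1
4	ROS1	G365A	1	1	1
4	TP53	L17R	1	1	1
4	TP53	L198R	1	1	1
4	TP53	L330R	1	1	1
5	BARD1	R207C	1	1	1
5	TP53	V125G	1	0	0
5	TP53	V86G	1	0	0
5	TP53	V218G	1	0	0
6	RAD51B	T107K	1	0	0
6	ALK	R405H	0	0	1
6	ALK	R1575H	0	0	1
6	ATM	L89F	0	0	1
7	ATM	L89F	1	1	1
7	BRAF	L319I	1	0	0
7	CHEK2	K373E	1	0	0
7	CHEK2	K117E	1	0	0
7	CHEK2	K344E	1	0	0
7	CHEK2	K152E	1	0	0
7	CHEK2	K416E	1	0	0
7	CHEK2	K282E	1	0	0
7	FGFR3	P449S	1	1	1
7	FGFR3	P450S	1	1	1
7	FGFR3	P451S	1	1	1
7	NF1	D109E	1	1	1
7	RAD51B	T107K	1	0	0
7	TP53	V157F	1	0	0
7	TP53	V25F	1	0	0
7	TP53	V64F	1	0	0
8	BRAF	L319I	1	0	0
9	BRAF	L319I	0	1	0
9	TP53	Y163C	1	0	0
9	TP53	Y31C	1	0	0
9	TP53	Y70C	1	0	0
10	ATM	P1054R	1	1	1
10	BRAF	L319I	0	1	0
10	PTEN	Y27C	1	1	1
10	RAD51B	T107K	0	1	0
10	TP53	S127Y	1	1	1
10	TP53	S34Y	1	1	1
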