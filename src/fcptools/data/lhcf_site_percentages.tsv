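species	site_id	pigment_class	ligand_class	residues	conserved	percent	n_lhcf
P_tricornutum	Chl a401	chl_a	central	P	true	35	17
P_tricornutum	Chl a401	chl_a	h_bond	N	true	77	17
P_tricornutum	Chl a401	chl_a	h_bond	Q	true	65	17
P_tricornutum	Chl a402	chl_a	central	E	true	100	17
P_tricornutum	Chl a402	chl_a	h_bond	F	true	59	17
P_tricornutum	Chl c403	chl_c	central	H	true	100	17
P_tricornutum	Chl c403	chl_c	h_bond	R	true	71	17
P_tricornutum	Chl a404	chl_a	central	Q	true	47	17
P_tricornutum	Chl a404	chl_a	central	T or V	false	53	17
P_tricornutum	Chl a404	chl_a	h_bond	L	true	24	17
P_tricornutum	Chl a405	chl_a	central	Q	true	88	17
P_tricornutum	Chl a405	chl_a	central	A or T	false	12	17
P_tricornutum	Chl a405	chl_a	h_bond	G	true	94	17
P_tricornutum	Chl a406	chl_a	central	E	true	82	17
P_tricornutum	Chl a406	chl_a	central	D	false	18	17
P_tricornutum	Chl a406	chl_a	h_bond	K	true	100	17
P_tricornutum	Chl a407	chl_a	central	E	true	100	17
P_tricornutum	Chl a407	chl_a	h_bond	F	true	65	17
P_tricornutum	Chl c408	chl_c	central	Q	true	65	17
P_tricornutum	Chl c408	chl_c	central	N or H	false	35	17
P_tricornutum	Chl c408	chl_c	h_bond	K	true	65	17
P_tricornutum	Chl a409	chl_a	central	H	true	88	17
P_tricornutum	Chl a409	chl_a	central	E or S	false	12	17
P_tricornutum	Fx301	fx	central	L	true	77	17
P_tricornutum	Fx302	fx	central	R	true	100	17
P_tricornutum	Fx302	fx	central	T	true	24	17
P_tricornutum	Fx302	fx	central	Y	true	25	17
P_tricornutum	Fx302	fx	central	M	true	71	17
P_tricornutum	Fx303	fx	central	F	true	59	17
P_tricornutum	Fx303	fx	central	G	true	94	17
P_tricornutum	Fx304	fx	central	K	true	65	17
P_tricornutum	Fx305	fx	central	L	true	24	17
T_lutea	Chl a401	chl_a	central	P	true	61	28
T_lutea	Chl a401	chl_a	h_bond	N	true	43	28
T_lutea	Chl a401	chl_a	h_bond	Q	true	0	28
T_lutea	Chl a402	chl_a	central	E	true	89	28
T_lutea	Chl a402	chl_a	h_bond	F	true	29	28
T_lutea	Chl c403	chl_c	central	H	true	89	28
T_lutea	Chl c403	chl_c	h_bond	R	true	50	28
T_lutea	Chl a404	chl_a	central	Q	true	14	28
T_lutea	Chl a404	chl_a	central	T or V	false	43	28
T_lutea	Chl a404	chl_a	h_bond	L	true	29	28
T_lutea	Chl a405	chl_a	central	Q	true	89	28
T_lutea	Chl a405	chl_a	central	A or T	false	0	28
T_lutea	Chl a405	chl_a	h_bond	G	true	71	28
T_lutea	Chl a406	chl_a	central	E	true	75	28
T_lutea	Chl a406	chl_a	central	D	false	18	28
T_lutea	Chl a406	chl_a	h_bond	K	true	89	28
T_lutea	Chl a407	chl_a	central	E	true	93	28
T_lutea	Chl a407	chl_a	h_bond	F	true	14	28
T_lutea	Chl c408	chl_c	central	Q	true	0	28
T_lutea	Chl c408	chl_c	central	N or H	false	93	28
T_lutea	Chl c408	chl_c	h_bond	K	true	68	28
T_lutea	Chl a409	chl_a	central	H	true	61	28
T_lutea	Chl a409	chl_a	central	E or S	false	4	28
T_lutea	Fx301	fx	central	L	true	50	28
T_lutea	Fx302	fx	central	R	true	93	28
T_lutea	Fx302	fx	central	T	true	0	28
T_lutea	Fx302	fx	central	Y	true	54	28
T_lutea	Fx302	fx	central	M	true	0	28
T_lutea	Fx303	fx	central	F	true	29	28
T_lutea	Fx303	fx	central	G	true	68	28
T_lutea	Fx304	fx	central	K	true	68	28
T_lutea	Fx305	fx	central	L	true	18	28
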