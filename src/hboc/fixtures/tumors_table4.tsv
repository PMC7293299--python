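case_id	gene	variant_label	tumor_id	age_at_surgery	histology	hormonal_subtype	nuclear_grade	wildtype_loss
A1013	PALB2	p.M723fs	T1	36	Solid Tubular	Luminal	1	NA
A0139	PALB2	p.R1086*	T1	63	Scirrhous	Luminal	3	AST
B0215	PALB2	p.R1086*	T1	37	Solid Tubular	Luminal-HER2	3	NA
A0214	PALB2	p.E462*	T1	50	Scirrhous	Luminal	.	AST
A0214	PALB2	p.E462*	T2	55	Scirrhous	Luminal-HER2	1	NA
B0219	PALB2	p.E462*	T1	54	Solid Tubular	Luminal	2	AST
B0219	PALB2	p.E462*	T2	58	Non-invasive Ductal	Triple Negative	1	LOH
B0219	PALB2	p.E462*	T3	61	Solid Tubular	Triple Negative	3	NA
B0277	PALB2	p.L484*	T1	47	Scirrhous	Triple Negative	3	AST
A0338	PALB2	p.T274fs	T1	44	Scirrhous	Luminal	3	NA
A0338	PALB2	p.T274fs	T2	44	Scirrhous	Luminal	3	NA
E0125	ATM	p.P80fs	T1	47	Mucinous	Luminal	.	LOH
A0346	ATM	p.Q374fs	T1	65	Scirrhous	Luminal	1	NA
B0242	ATM	c.4776+2T>A	T1	49	Scirrhous	Luminal	2	ND
C0158	ATM	p.F1837fs	T1	48	Solid Tubular	Luminal	2	LOH
A0301	BARD1	p.R641*	T1	58	Solid Tubular	Triple Negative	3	NA
A0331	BARD1	p.R150*	T1	26	Scirrhous	Luminal	3	NA
A0331	ATM	p.A2626fs	T2	.	.	.	.	NA
A0298	BARD1	p.Q449*	T1	35	Scirrhous	Triple Negative	3	NA
B0258	BARD1	p.A173fs	T1	42	Solid Tubular	Triple Negative	3	LOH
B0258	BARD1	p.A173fs	T2	57	Solid Tubular	Triple Negative	3	NA
E0114	BARD1	Exon 5-7 Deletion	T1	42	Papillotubular	Luminal (Unk. HER2)	1	NA
E0114	BARD1	Exon 5-7 Deletion	T2	51	Tubular	Luminal (Unk. HER2)	1	NA
E0114	BARD1	Exon 5-7 Deletion	T3	64	Scirrhous	.	2	ND
C0120	RAD51D	p.K111fs	T1	33	Papillotubular	Luminal	3	LOH
A0231	RAD51D	p.V152fs	T1	40	Non-invasive Ductal	Luminal (Unk. HER2)	2	ND
A0231	RAD51D	p.V152fs	T2	47	Non-invasive Ductal	Luminal	1	NA
B0220	RAD51D	p.Q149*	T1	39	Scirrhous	Luminal	2	ND
D0221	BLM	p.S106fs	T1	40	Non-invasive Ductal	Luminal (Unk. HER2)	.	NA
C0256	BLM	p.S106fs	T1	49	Scirrhous	Luminal	2	NA
C0256	BLM	p.S106fs	T2	49	Solid Tubular	Luminal	2	NA
B0187	BLM	p.G512fs	T1	49	Solid Tubular	Luminal	1	ND
B0292	BLM	c.3751+2T>C	T1	49	Scirrhous	Luminal	1	NA
A0281	BRIP1	p.R356*	T1	33	Mucinous	Luminal	1	NA
B0285	BRIP1	p.A1081fs	T1	47	Non-invasive Ductal	Luminal	1	LOH
B0285	BRIP1	p.A1081fs	T2	47	Papillotubular	Luminal	1	NA
B0170	BRIP1	c.918+2T>C	T1	41	Scirrhous	Luminal	1	NA
B0170	BRIP1	c.918+2T>C	T2	41	Non-invasive Ductal	Luminal (Unk. HER2)	.	ND
E0237	RAD51C	p.E45*	T1	50	Scirrhous	Luminal	2	NA
C0206	RAD51C	Exon 6-9 Deletion	T1	51	Scirrhous	Triple Negative	2	LOH
B0263	RAD51C	Exon 6-9 Deletion	T1	45	Scirrhous	Luminal (Unk. HER2)	.	NA
B0263	RAD51C	Exon 6-9 Deletion	T2	45	Non-invasive Ductal	.	.	ND
B0288	FANCM	p.Q730fs	T1	34	Solid Tubular	Triple Negative	3	ND
D0231	FANCM	p.K841fs	T1	41	Non-invasive Ductal	Luminal	1	NA
E0131	RAD50	p.D544fs	T1	49	Scirrhous	Luminal-HER2	3	ND
B0198	NF1	p.G255fs	T1	25	Solid Tubular	Luminal	2	LOH
A0277	CHEK2	p.L486fs	T1	37	Papillotubular	Luminal	1	ND
D0222	RECQL	p.D517_S518delins*	T1	57	Solid Tubular	.	.	NA
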