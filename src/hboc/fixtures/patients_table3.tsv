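case_id	gene	variant_label	history_level	primary_site	age_at_primary_dx	laterality	additional_cancer
A1013	PALB2	p.M723fs	1	Breast	36	Unilateral (n=1)	.
A0139	PALB2	p.R1086*	1	Breast	63	Unilateral (n=1)	.
B0215	PALB2	p.R1086*	2	Breast	37	Unilateral (n=1)	.
A0214	PALB2	p.E462*	2	Breast	50	Bilateral (n>=2)	.
B0219	PALB2	p.E462*	1	Breast	54	Bilateral (n>=2)	Thyroid
B0277	PALB2	p.L484*	2	Breast	47	Unilateral (n=1)	.
A0338	PALB2	p.T274fs	2	Breast	44	Bilateral (n>=2)	.
D0241	ATM	p.R805*	2	Ovary	50	Not applicable	.
E0125	ATM	p.P80fs	2	Breast	47	Unilateral (n=1)	.
A0346	ATM	p.Q374fs	1	Breast	65	Unilateral (n=1)	.
B0242	ATM	c.4776+2T>A	2	Breast	49	Unilateral (n=1)	.
C0158	ATM	p.F1837fs	2	Breast	48	Unilateral (n=1)	.
A0301	BARD1	p.R641*	2	Breast	58	Unilateral (n=1)	.
A0331	BARD1	p.R150*	2	Breast	26	Unilateral (n=1)	.
A0331	ATM	p.A2626fs	2	Breast	26	Unilateral (n=1)	.
A0298	BARD1	p.Q449*	1	Breast	35	Unilateral (n=1)	.
B0258	BARD1	p.A173fs	2	Breast	42	Bilateral (n>=2)	.
E0114	BARD1	Exon 5-7 Deletion	1	Breast	42	Bilateral (n>=2)	Endometrial
C0120	RAD51D	p.K111fs	1	Breast	33	Unilateral (n=1)	.
D0239	RAD51D	p.K111fs	2	Ovary	58	Not applicable	.
A0231	RAD51D	p.V152fs	1	Breast	40	Bilateral (n>=2)	.
B0220	RAD51D	p.Q149*	2	Breast	39	Unilateral (n=1)	.
D0221	BLM	p.S106fs	1	Breast	40	Unilateral (n=1)	.
C0256	BLM	p.S106fs	1	Breast	49	Bilateral (n>=2)	.
B0187	BLM	p.G512fs	1	Breast	49	Unilateral (n=1)	.
B0292	BLM	c.3751+2T>C	2	Breast	49	Unilateral (n=1)	.
A0281	BRIP1	p.R356*	1	Breast	33	Unilateral (n=1)	.
B0285	BRIP1	p.A1081fs	1	Breast	47	Bilateral (n>=2)	.
B0170	BRIP1	c.918+2T>C	1	Breast	41	Unilateral (n>=2)	Thyroid
E0237	RAD51C	p.E45*	2	Breast	50	Unilateral (n=1)	.
C0206	RAD51C	Exon 6-9 Deletion	2	Breast	51	Unilateral (n=1)	.
B0263	RAD51C	Exon 6-9 Deletion	2	Breast	45	Bilateral (n>=2)	.
B0288	FANCM	p.Q730fs	2	Breast	34	Unilateral (n=1)	.
D0231	FANCM	p.K841fs	2	Breast	41	Unilateral (n=1)	.
E0131	RAD50	p.D544fs	2	Breast	49	Unilateral (n=1)	.
B0198	NF1	p.G255fs	1	Breast	25	Unilateral (n=1)	.
A0277	CHEK2	p.L486fs	1	Breast	37	Unilateral (n=1)	.
D0222	RECQL	p.D517_S518delins*	2	Breast	57	Unilateral (n=1)	.
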