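case_id	gene	hgvs_c	hgvs_p	clinvar	hgmd	hgvd	tmm	exac_east_asian	exac_other
A1013	PALB2	c.2167_2168del	p.M723fs	Present	Present	NR	NR	NR	7/98344
A0139	PALB2	c.C3256T	p.R1086*	Present	Present	NR	NR	NR	1/98344
B0215	PALB2	c.C3256T	p.R1086*	Present	Present	NR	NR	NR	1/98344
A0214	PALB2	c.G1384T	p.E462*	NR	NR	NR	NR	NR	NR
B0219	PALB2	c.G1384T	p.E462*	NR	NR	NR	NR	NR	NR
B0277	PALB2	c.T1451G	p.L484*	NR	NR	NR	NR	NR	NR
A0338	PALB2	c.820dupA	p.T274fs	NR	NR	NR	NR	NR	NR
D0241	ATM	c.C2413T	p.R805*	Present	Present	NR	NR	3/7844	2/98354
E0125	ATM	c.240dupA	p.P80fs	NR	NR	NR	NR	NR	NR
A0346	ATM	c.1121_1122del	p.Q374fs	NR	NR	2/600	1/7108	NR	NR
B0242	ATM	c.4776+2T>A	Splicing	NR	Present	NR	NR	NR	NR
C0158	ATM	c.5509_5510del	p.F1837fs	NR	NR	NR	NR	NR	NR
A0301	BARD1	c.C1921T	p.R641*	Present	Present	NR	NR	NR	1/98342
A0331	BARD1	c.C448T	p.R150*	Present	NR	NR	NR	NR	1/98348
A0331	ATM	c.7878_7882del	p.A2626fs	Present	Present	NR	4/7108	NR	NR
A0298	BARD1	c.C1345T	p.Q449*	NR	NR	NR	NR	NR	NR
B0258	BARD1	c.518dupC	p.A173fs	NR	NR	NR	NR	NR	NR
E0114	BARD1	Exon 5-7 Deletion	.	NR	NR	NA	NA	NR	NR
C0120	RAD51D	c.331_332insTA	p.K111fs	Present	Present	1/858	5/7108	9/7866	NR
D0239	RAD51D	c.331_332insTA	p.K111fs	Present	Present	1/858	5/7108	9/7866	NR
A0231	RAD51D	c.454delG	p.V152fs	NR	NR	NR	NR	NR	NR
B0220	RAD51D	c.C445T	p.Q149*	NR	NR	NR	NR	NR	NR
D0221	BLM	c.319dupT	p.S106fs	NR	NR	1/858	1/7108	1/7856	NR
C0256	BLM	c.319dupT	p.S106fs	NR	NR	1/858	1/7108	1/7856	NR
B0187	BLM	c.1536dupA	p.G512fs	Present	Present	NR	4/7108	NR	13/98522
B0292	BLM	c.3751+2T>C	Splicing	NR	NR	NR	1/7102	NR	NR
A0281	BRIP1	c.C1066T	p.R356*	Present	Present	NR	NR	NR	NR
B0285	BRIP1	c.3240dupT	p.A1081fs	NR	NR	1/858	2/7108	1/7866	NR
B0170	BRIP1	c.918+2T>C	Splicing	NR	NR	NR	NR	NR	NR
E0237	RAD51C	c.G133T	p.E45*	NR	NR	NR	NR	NR	NR
C0206	RAD51C	Exon 6-9 Deletion	.	NR	NR	NA	NA	NR	NR
B0263	RAD51C	Exon 6-9 Deletion	.	NR	NR	NA	NA	NR	NR
B0288	FANCM	c.2190_2191insCT	p.Q730fs	NR	NR	NR	NR	NR	NR
D0231	FANCM	c.2521_2524del	p.K841fs	NR	NR	1/858	1/7108	NR	2/98370
E0131	RAD50	c.1633dupA	p.D544fs	NR	NR	NR	NR	NR	NR
B0198	NF1	c.765delT	p.G255fs	NR	NR	NR	NR	NR	NR
A0277	CHEK2	c.1455dupG	p.L486fs	NR	NR	NR	NR	NR	NR
D0222	RECQL	c.1548dupT	p.D517_S518delins*	NR	NR	NR	1/7108	NR	NR
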