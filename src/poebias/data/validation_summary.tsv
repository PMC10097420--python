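gene_id	chrom	datasets	reported_direction	gene_class	e16.5_placenta	e16.5_liver	e16.5_brain	P7_cortex	P7_hypothalamus	P7_cerebellum	P7_hippocampus	P7_brainstem	P60_cortex	P60_hypothalamus	P60_cerebellum	P60_hippocampus	P60_brainstem	strain_bias	reported_status
L3mbtl1	2	B	pat	1	NA	NA	NA	48.1	53.4	53.4	46.4	50.1	49.4	49.7	46.7	51.0	49.2	1	Biallelic
Ahi1	10	B,D	pat	1	52.8	46.5	NA	47.0	51.6	50.9	52.8	46.9	48.6	49.4	50.0	52.4	51.3	1	Biallelic
Platr20	11	A	pat	1	51.7	49.9	50.0	49.9	50.4	50.1	50.4	50.2	49.8	49.8	50.1	50.2	49.7	0	Biallelic
Calm1	12	B,D	pat	1	NA	NA	NA	54.7	49.5	51.4	45.9	43.4	NA	NA	NA	NA	NA	1	Biallelic
Nhlrc1	13	B,C,D	pat	1	NA	NA	NA	56.6	55.6	57.8	54.8	58.8	58.1	56.1	55.4	55.0	55.2	1	Paternal
Tnk1	11	A	mat	1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Mlana	18	B	mat	1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Gm16299	19	C	pat	1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Stx6	1	C	mat	2	NA	NA	NA	50.7	49.2	50.3	49.8	50.1	NA	NA	NA	NA	NA	0	Biallelic
Gabra5	7	B,D	pat	2	NA	NA	NA	51.5	53.2	52.5	54.8	52.6	52.3	50.7	48.6	51.5	51.5	0	Biallelic
Wnk4	11	C	mat	2	NA	NA	NA	50.1	52.0	45.3	50.6	44.0	48.1	44.6	50.9	45.4	48.1	1	Maternal
Vat1	11	B	mat	2	43.9	50.9	52.6	49.6	48.8	50.4	51.0	49.9	46.4	51.3	50.8	49.8	50.4	1	Placental
Rdm1	11	A	mat	2	49.4	NA	NA	48.8	48.8	50.1	50.2	50.7	46.9	49.5	50.5	50.1	48.7	1	Biallelic
Gaa	11	B,D	pat	2	48.9	52.3	53.6	51.3	47.1	51.7	53.1	51.8	51.8	51.6	47.9	51.9	50.8	1	Biallelic
Pcdhb10	18	D	mat	2	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Pcdhb12	18	B,C	mat	2	NA	NA	NA	40.5	41.2	41.0	39.4	41.8	42.6	42.7	42.1	43.2	44.9	0	Maternal
Pcdhb20	18	B,C	pat	2	NA	NA	52.7	51.5	51.6	52.0	52.6	53.1	51.5	52.3	51.6	51.6	50.1	1	Biallelic
Prdx5	19	B	pat	2	46.9	51.1	49.4	49.0	50.4	48.8	49.4	49.9	49.2	50.2	50.0	48.3	49.2	1	Biallelic
Rtn3	19	D	pat	2	44.6	49.9	50.7	49.4	47.3	49.5	49.5	49.2	49.1	50.9	49.7	50.4	50.4	0	Placental
Pla2g16	19	B	mat	2	40.3	51.6	50.6	51.7	49.7	48.9	48.5	50.7	51.5	51.2	49.2	46.8	48.3	1	Placental
Mr1	1	C	mat	2	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
BC034090	1	C	mat	2	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Tmem106a	11	A	mat	2	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Adam23	1	A,B,C,D	pat	3	48.0	52.0	59.1	56.5	57.8	56.5	58.0	53.7	55.6	58.7	53.5	56.5	54.1	0	Paternal
Mcts2	2	A,B,C	pat	K	77.2	82.9	64.7	71.8	80.2	73.1	77.3	80.4	85.7	78.3	70.6	87.8	84.2	0	Paternal
Cox4i2	2	C	pat	3	49.3	NA	NA	69.8	51.0	56.6	60.0	56.5	55.3	55.0	52.8	56.8	54.9	0	Paternal
Bcl2l1	2	A,B,C,D	pat	3	49.5	50.2	61.6	60.9	61.8	58.3	59.5	58.8	59.9	61.4	57.4	59.2	59.0	0	Paternal
Tpx2	2	C	pat	3	NA	49.7	49.1	53.4	52.6	50.7	53.6	51.4	56.4	55.4	64.6	62.5	61.1	1	Paternal
Herc3	6	A,B,C,D	mat	K	47.0	45.8	43.1	45.7	40.7	40.5	49.9	32.4	44.0	29.5	39.0	42.3	24.4	1	Maternal
Fam13a	6	B,D	mat	3	NA	46.1	53.2	47.9	47.1	51.3	49.4	48.4	NA	NA	NA	NA	NA	1	Biallelic
Zfp78	7	B	both	3	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Smim17	7	B,D	mat	3	NA	NA	38.3	48.8	35.5	50.9	44.0	44.5	45.2	43.2	52.1	50.8	49.3	0	Maternal
Peg3	7	A,B,C,D	pat	K	96.3	99.2	99.6	92.4	92.8	94.1	94.3	95.1	97.5	98.0	98.0	97.3	97.7	1	Paternal
Zfp954	7	B	mat	3	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Zfp773	7	B	mat	3	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Zfp772	7	B	mat	3	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	Low expression
Clcn4-2	7	B	mat	3	44.6	54.5	48.5	48.9	48.8	49.9	49.1	48.0	49.5	50.7	51.0	49.6	50.7	1	Placental
Ifitm10	7	C,D	mat	3	46.9	52.3	48.7	47.5	41.5	53.0	49.4	45.0	49.0	43.2	43.6	50.7	47.0	1	Maternal
Ctsd	7	B,D	mat	3	46.8	47.8	50.1	50.0	49.0	48.4	48.9	49.8	49.3	50.2	49.0	50.5	49.5	0	Biallelic
Evl	12	B	pat	3	46.2	48.3	50.2	48.7	51.3	51.1	50.2	49.5	50.9	50.9	52.6	50.8	50.6	1	Biallelic
Slc25a29	12	B	pat	3	18.9	45.5	52.3	53.9	56.2	54.5	53.3	54.2	52.8	53.8	50.6	53.6	53.2	1	Placental
Wars	12	C	pat	3	45.2	52.5	55.1	53.9	56.2	54.5	53.3	54.2	52.8	53.9	50.6	53.6	53.2	0	Paternal
Wdr25	12	B,D	pat	3	NA	NA	NA	50.7	52.9	52.0	50.6	48.7	51.8	59.8	49.9	51.7	NA	1	Paternal
Dlk1	12	A,B,C,D	pat	K	95.7	87.9	93.7	92.5	92.7	94.6	90.2	95.0	89.5	95.6	93.2	86.9	95.2	0	Paternal
Ppp2r5c	12	B,C	pat	3	52.4	51.3	48.5	48.6	49.3	54.0	50.6	48.2	50.6	48.7	45.2	51.0	49.3	1	Biallelic
Dync1h1	12	B,C	pat	3	46.9	49.8	50.4	50.7	50.7	51.1	49.9	50.4	51.0	50.4	50.1	50.1	49.8	0	Biallelic
Ago2	15	A,B,C,D	mat	3	47.7	50.7	30.1	24.1	25.8	28.8	28.7	19.3	25.9	28.7	38.0	33.3	24.6	0	Maternal
Ampd3	7	B	mat	K	23.4	47.5	51.4	48.6	48.5	48.3	51.8	50.9	50.1	46.7	50.9	49.4	51.5	1	Placental
Gab1	8	A	pat	K	74.9	50.4	49.8	52.7	49.6	48.6	49.4	51.0	47.1	49.6	48.8	50.1	50.2	0	Placental
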