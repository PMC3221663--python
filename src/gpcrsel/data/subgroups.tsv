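# Class A non-olfactory human GPCR subgroups with per-member natural-ligand
# chemistry and orphan status. chemical_class is one of small/lipid/peptide/
# other and is empty for orphan members (orphan=1). notes flags: N = max
# pairwise dN >= 1, S = max pairwise dS >= 3, o = subgroup contains orphan
# member(s).
subgroup_id	label	ligand	chemical_class	orphan	notes
1	CHRM1	acetylcholine	small	0	
1	CHRM2	acetylcholine	small	0	
1	CHRM3	acetylcholine	small	0	
1	CHRM4	acetylcholine	small	0	
1	CHRM5	acetylcholine	small	0	
2	DRD1	dopamine	small	0	
2	DRD2	dopamine	small	0	
2	DRD3	dopamine	small	0	
2	DRD4	dopamine	small	0	
2	DRD5	dopamine	small	0	
3	P2RY12	nucleotides	small	0	o,S
3	P2RY13	nucleotides	small	0	o,S
3	P2RY14	nucleotides	small	0	o,S
3	GPR87	nucleotides	small	0	o,S
3	GPR171			1	o,S
4	HTR1A	5-hydroxytryptamine	small	0	
4	HTR1B	5-hydroxytryptamine	small	0	
4	HTR1D	5-hydroxytryptamine	small	0	
4	HTR1F	5-hydroxytryptamine	small	0	
4	HTR1E	5-hydroxytryptamine	small	0	
4	HTR5A	5-hydroxytryptamine	small	0	
4	HTR7	5-hydroxytryptamine	small	0	
5	P2RY1	nucleotides	small	0	
5	P2RY2	nucleotides	small	0	
5	P2RY4	nucleotides	small	0	
5	P2RY6	nucleotides	small	0	
5	P2RY11	nucleotides	small	0	
6	MTNR1A	melatonin	small	0	o
6	MTNR1B	melatonin	small	0	o
6	GPR50			1	o
7	ADRA1A	adrenaline	small	0	
7	ADRA1B	adrenaline	small	0	
7	ADRB1	adrenaline	small	0	
7	ADRB2	adrenaline	small	0	
7	ADRB3	adrenaline	small	0	
8	HTR2A	5-hydroxytryptamine	small	0	
8	HTR2B	5-hydroxytryptamine	small	0	
8	HTR2C	5-hydroxytryptamine	small	0	
9	HRH1	histamine	small	0	
9	HRH2	histamine	small	0	
9	HRH3	histamine	small	0	
9	HRH4	histamine	small	0	
10	ADORA1	adenosine	small	0	
10	ADORA2A	adenosine	small	0	
10	ADORA2B	adenosine	small	0	
11	S1PR2	sphingosine 1-phosphate	lipid	0	
11	S1PR1	sphingosine 1-phosphate	lipid	0	
11	S1PR3	sphingosine 1-phosphate	lipid	0	
11	S1PR5	sphingosine 1-phosphate	lipid	0	
11	LPAR1	lysophosphatidic acid	lipid	0	
11	LPAR3	lysophosphatidic acid	lipid	0	
12	GPR3	sphingosine 1-phosphate	lipid	0	
12	GPR6	sphingosine 1-phosphate	lipid	0	
12	GPR12	sphingosine 1-phosphate	lipid	0	
13	FFAR1	free fatty acids	lipid	0	
13	FFAR2	free fatty acids	lipid	0	
13	FFAR3	free fatty acids	lipid	0	
13b	FFAR1	free fatty acids	lipid	0	
13b	FFAR2	free fatty acids	lipid	0	
13b	FFAR3	free fatty acids	lipid	0	
13b	GPR42	free fatty acids	lipid	0	
14	PTGDR	prostaglandins	lipid	0	
14	PTGER1	prostaglandins	lipid	0	
14	PTGER3	prostaglandins	lipid	0	
14	PTGER4	prostaglandins	lipid	0	
14	PTGFR	prostaglandins	lipid	0	
14	PTGIR	prostaglandins	lipid	0	
14	TBXA2R	thromboxane	lipid	0	
15	CYSLTR1	cysteinyl leukotrienes	lipid	0	
15	CYSLTR2	cysteinyl leukotrienes	lipid	0	
15	GPR17	cysteinyl leukotrienes	lipid	0	
16	LPAR4	lysophosphatidic acid	lipid	0	o
16	LPAR6	lysophosphatidic acid	lipid	0	o
16	GPR174			1	o
16	P2RY10	sphingosine 1-phosphate	lipid	0	o
16	PTAFR	platelet activating factor	lipid	0	o
17	RRH	retinoids	lipid	0	
17	OPN3	retinoids	lipid	0	
17	OPN4	retinoids	lipid	0	
17	OPN5	retinoids	lipid	0	
17	RGR	retinoids	lipid	0	
18	OPN1MW	retinoids	lipid	0	
18	OPN1LW	retinoids	lipid	0	
18	RHO	retinoids	lipid	0	
18	OPN1SW	retinoids	lipid	0	
19	GPR81	hydroxylated fatty acids	lipid	0	
19	GPR109B	hydroxylated fatty acids	lipid	0	
19	GPR109A	hydroxylated fatty acids	lipid	0	
20	TACR1	tachykinin neuropeptides	peptide	0	
20	TACR2	tachykinin neuropeptides	peptide	0	
20	TACR3	tachykinin neuropeptides	peptide	0	
21	TSHR	glycoprotein hormones	peptide	0	
21	LHCGR	glycoprotein hormones	peptide	0	
21	FSHR	glycoprotein hormones	peptide	0	
22	F2R	unmasked N-terminus	peptide	0	
22	F2RL1	unmasked N-terminus	peptide	0	
22	F2RL2	unmasked N-terminus	peptide	0	
22	F2RL3	unmasked N-terminus	peptide	0	
23	GPR83			1	o
23	NPY1R	neuropeptide Y	peptide	0	o
23	NPY2R	neuropeptide Y	peptide	0	o
23	PPYR1	peptide YY	peptide	0	o
23	NPY5R	neuropeptide Y	peptide	0	o
24	C3AR1	anaphylatoxins	peptide	0	
24	C5AR1	anaphylatoxins	peptide	0	
24	GPR77	anaphylatoxins	peptide	0	
25	EDNRA	endothelins	peptide	0	o
25	EDNRB	endothelins	peptide	0	o
25	GPR37			1	o
25	GPR37L1			1	o
26	LGR5			1	o
26	LGR6			1	o
26	RXFP1	relaxin	peptide	0	o
26	RXFP2	relaxin	peptide	0	o
27	GALR1	galanin	peptide	0	N
27	GALR2	galanin	peptide	0	N
27	GALR3	galanin	peptide	0	N
28	OPRL1	opioid peptides	peptide	0	N
28	OPRM1	opioid peptides	peptide	0	N
28	OPRD1	opioid peptides	peptide	0	N
28	OPRK1	opioid peptides	peptide	0	N
29	SSTR2	somatostatins	peptide	0	
29	SSTR3	somatostatins	peptide	0	
29	SSTR5	somatostatins	peptide	0	
30	GRPR	bombesin-related peptides	peptide	0	
30	NMBR	bombesin-related peptides	peptide	0	
30	BRS3	bombesin-related peptides	peptide	0	
31	MC3R	melanocortins	peptide	0	N
31	MC4R	melanocortins	peptide	0	N
31	MC5R	melanocortins	peptide	0	N
32	AVPR1A	vasopressin	peptide	0	N
32	AVPR1B	vasopressin	peptide	0	N
32	AVPR2	vasopressin	peptide	0	N
33	CXCR1	chemokines	peptide	0	
33	CXCR2	chemokines	peptide	0	
33	CXCR3	chemokines	peptide	0	
33	CXCR4	chemokines	peptide	0	
33	CXCR5	chemokines	peptide	0	
33	CXCR6	chemokines	peptide	0	
33	CCR6	chemokines	peptide	0	
33	CCR7	chemokines	peptide	0	
33	CCR9	chemokines	peptide	0	
33	CCR10	chemokines	peptide	0	
34	APLNR	apelin	peptide	0	
34	AGTR1	angiotensin	peptide	0	
34	RL3R1	relaxin	peptide	0	
34	RXFP4	relaxin	peptide	0	
35	NTSR1	neurotensin	peptide	0	
35	NTSR2	neurotensin	peptide	0	
35	GPR39	obestatin	peptide	0	
36	CCR1	chemokines	peptide	0	S
36	CCR2	chemokines	peptide	0	S
36	CCR3	chemokines	peptide	0	S
36	CCR4	chemokines	peptide	0	S
36	CCR5	chemokines	peptide	0	S
36	CCR8	chemokines	peptide	0	S
36	CCRL2	chemokines	peptide	0	S
36	CX3CR1	chemokines	peptide	0	S
36	CCBP2	chemokines	peptide	0	S
37	FPR1	N-formyl-methionyl peptides	peptide	0	
37	FPR2	N-formyl-methionyl peptides	peptide	0	
37	FPR3	N-formyl-methionyl peptides	peptide	0	
38	MRGPRX1	enkephalins	peptide	0	o
38	MRGPRX2	cortistatins	peptide	0	o
38	MRGPRX3			1	o
38	MRGPRX4			1	o
39	GPR101			1	o
39	GPR161			1	o
39	GPR135			1	o
39	GPR63	sphingosine 1-phosphate	lipid	0	o
39	GPR45			1	o
40	GPR4	protons	other	0	N
40	GPR65	glycosphingolipids	lipid	0	N
40	GPR68	protons	other	0	N
41	MAS1	angiotensin	peptide	0	o
41	MAS1L			1	o
41	MRGPRD	beta-alanine	small	0	o
41	MRGPRF			1	o
42	TAAR1	trace amines	small	0	o,S
42	TAAR5			1	o,S
42	TAAR6			1	o,S
42	TAAR8			1	o,S
42	TAAR9			1	o,S
43	C3AR1	anaphylatoxins	peptide	0	
43	C5AR1	anaphylatoxins	peptide	0	
43	GPR77	anaphylatoxins	peptide	0	
43	CMKLR1	chemerin	peptide	0	
43	FPR1	N-formyl-methionyl peptides	peptide	0	
43	FPR2	N-formyl-methionyl peptides	peptide	0	
43	FPR3	N-formyl-methionyl peptides	peptide	0	
43	GPR1	chemerin	peptide	0	
43	GPR32	resolvins	lipid	0	
43	GPR44	prostanoids	lipid	0	
44	MAS1	angiotensin	peptide	0	o
44	MAS1L			1	o
44	MRGPRD	beta-alanine	small	0	o
44	MRGPRF			1	o
44	MRGPRX1	enkephalins	peptide	0	o
44	MRGPRX2	cortistatins	peptide	0	o
44	MRGPRX3			1	o
44	MRGPRX4			1	o
45	GPR27			1	o
45	GPR85			1	o
45	GPR173			1	o
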