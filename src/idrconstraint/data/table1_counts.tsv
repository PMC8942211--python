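region_id	gene	start	end	length	frameshift_pathogenic	frameshift_population	nonsense_pathogenic	nonsense_population	missense_pathogenic	missense_population	inframe_pathogenic	inframe_population
BMPR1A_24_54	BMPR1A	24	54	31	5	0	1	0	0	12	2	0
BRCA2_21_39	BRCA2	21	39	19	11	0	13	2	1	24	2	0
CDKN1B_1_198	CDKN1B	1	198	198	8	7	7	1	1	179	0	2
CDKN1B_25_90	CDKN1B	25	90	66	4	2	5	0	1	52	0	1
CDKN1B_55_95	CDKN1B	55	95	41	3	1	4	0	1	52	0	1
CDKN1C_27_97	CDKN1C	27	97	71	2	0	1	4	0	68	0	0
CDKN2A_1_37	CDKN2A	1	37	37	1	4	3	0	0	62	0	0
COL7A1_1940_1978	COL7A1	1940	1978	39	2	0	1	0	1	23	0	0
CSTB_1_67	CSTB	1	67	67	1	1	3	1	3	46	0	1
DDX3X_1_167	DDX3X	1	167	167	7	0	6	0	5	0	0	0
EMD_1_187	EMD	1	187	187	11	0	10	0	5	76	2	3
EMD_67_170	EMD	67	170	104	4	0	4	0	0	50	2	1
KIT_544_565	KIT	544	565	22	1	0	3	1	21	7	14	0
LDLR_163_175	LDLR	163	175	13	3	0	5	2	14	11	1	0
LDLR_354_393	LDLR	354	393	40	13	1	10	2	37	33	4	0
MECP2_1_75	MECP2	1	75	75	21	0	10	0	2	26	0	1
MECP2_165_210	MECP2	165	210	46	13	0	13	0	2	46	1	1
MECP2_207_310	MECP2	207	310	104	77	0	13	0	14	60	4	0
MECP2_261_330	MECP2	261	330	70	40	0	4	0	12	42	4	0
NFKBIA_1_66	NFKBIA	1	66	66	0	0	4	1	7	31	0	2
PAX6_1_130	PAX6	1	130	130	18	3	12	0	23	69	0	0
RAF1_233_259	RAF1	233	259	27	0	0	0	0	12	7	0	0
RB1_245_269	RB1	245	269	25	4	0	2	0	0	15	0	0
RB1_346_370	RB1	346	370	25	3	0	1	0	0	11	0	1
RB1_355_370	RB1	355	370	16	2	0	1	0	0	8	0	1
RB1_500_511	RB1	500	511	12	2	0	1	0	0	1	0	0
RB1_500_513	RB1	500	513	14	2	1	1	0	0	2	0	0
RB1_577_615	RB1	577	615	39	2	0	4	0	0	22	0	0
RB1_786_928	RB1	786	928	143	6	0	12	0	1	65	0	1
SMAD4_297_306	SMAD4	297	306	10	1	0	3	0	0	4	0	0
SUFU_279_360	SUFU	279	360	82	2	1	1	0	0	58	0	0
TP53_60_92	TP53	60	92	33	17	0	4	0	0	36	0	2
TP53_291_312	TP53	291	312	22	8	4	4	0	2	26	1	0
WAS_201_268	WAS	201	268	68	2	0	3	1	1	17	0	1
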