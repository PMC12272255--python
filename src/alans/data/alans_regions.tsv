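network	abbreviation	region	hemisphere	x	y	z
Visu	CAL2	Calcarine Gyrus (2)	Right	10	-78	9
Visu	CAL3	Calcarine Gyrus (3)	Right	11	-94	1
Visu	FUS6	Fusiform Gyrus (6)	Right	29	-62	-9
Visu	FUS7	Fusiform Gyrus (7)	Right	23	-80	-8
Visu	LING2	Lingual Gyrus (2)	Right	21	-60	-6
Visu	LING4	Lingual Gyrus (4)	Right	13	-72	-9
Visu	LING6	Lingual Gyrus (6)	Right	7	-79	-3
Visu	O2_2	Middle Occipital Gyrus (2)	Right	41	-73	12
Visu	O3_2	Inferior Occipital Gyrus (2)	Right	47	-65	-7
Visu	Olat2	lateral occipital Gyrus (2)	Right	28	-89	-2
Visu	Olat4	lateral occipital Gyrus (4)	Right	34	-85	9
Visu	Olat5	lateral occipital Gyrus (5)	Right	36	-76	2
Somato-motor	cing4	cingulate sulcus (4)	Left	-8	-6	57
Somato-motor	cing5	cingulate sulcus (5)	Left	-8	-16	42
Somato-motor	cing7	cingulate sulcus (7)	Left	-9	-41	60
Somato-motor	INSp	Posterior Insula Gyrus	Left	-42	-19	14
Somato-motor	P1_1	Superior Parietal Gyrus (1)	Left	-24	-47	60
Somato-motor	P1_2	Superior Parietal Gyrus (2)	Left	-19	-47	68
Somato-motor	P1_3	Superior Parietal Gyrus (3)	Left	-30	-51	67
Somato-motor	P1_5	Superior Parietal Gyrus (5)	Left	-16	-61	61
Somato-motor	pCENT1	Paracentral Lobule Gyrus (1)	Left	-7	-17	51
Somato-motor	pCENT2	Paracentral Lobule Gyrus (2)	Left	-10	-29	66
Somato-motor	post1	postcentral sulcus (1)	Left	-58	-18	32
Somato-motor	post2	postcentral sulcus (2)	Left	-41	-33	55
Somato-motor	post3	postcentral sulcus (3)	Left	-43	-33	44
Somato-motor	prec2	precentral sulcus (2)	Left	-25	-8	59
Somato-motor	prec3	precentral sulcus (3)	Left	-18	-9	69
Somato-motor	prec6	precentral sulcus (6)	Left	-30	-11	65
Somato-motor	rol1	Rolandic fissure (1)	Left	-54	-8	32
Somato-motor	rol2	Rolandic fissure (2)	Left	-44	-14	51
Somato-motor	rol3	Rolandic fissure (3)	Left	-39	-23	61
Somato-motor	rol4	Rolandic fissure (4)	Left	-23	-29	65
Somato-motor	ROLop2	Rolandic Operculum (2)	Left	-51	-9	14
Somato-motor	SMG1	Supramarginal Gyrus (1)	Left	-54	-30	21
Somato-motor	T1_1	Superior Temporal Gyrus (1)	Left	-55	-1	2
Somato-motor	T1_2	Superior Temporal Gyrus (2)	Left	-45	-11	-2
Somato-motor	T1_3	Superior Temporal Gyrus (3)	Left	-52	-27	11
Posterior-medial	CINGp1	Posterior Cingulate Gyrus (1)	Right	5	-26	29
Posterior-medial	FUS4	Fusiform Gyrus (4)	Right	44	-46	-18
Posterior-medial	FUS5	Fusiform Gyrus (5)	Right	32	-47	-11
Posterior-medial	HIPP2	Hippocampus Gyrus (2)	Right	25	-31	-2
Posterior-medial	ios	intraoccipital sulcus (1)	Right	28	-69	33
Posterior-medial	ips3	intraparietal sulcus (3)	Right	26	-62	46
Posterior-medial	LING1	Lingual Gyrus (1)	Right	20	-44	-4
Posterior-medial	O2_1	Middle Occipital Gyrus (1)	Right	36	-74	25
Posterior-medial	O2_4	Middle Occipital Gyrus (4)	Right	41	-74	30
Posterior-medial	pHIPP2	Parahippocampal Gyrus (2)	Right	29	-25	-19
Posterior-medial	pHIPP4	Parahippocampal Gyrus (4)	Right	17	-27	-10
Posterior-medial	pHIPP5	Parahippocampal Gyrus (5)	Right	27	-36	-12
Posterior-medial	poleT2_3	Middle Tempora Pole Gyrus (3)	Right	26	6	-36
Posterior-medial	pos1	parieto-occipital sulcus (1)	Right	13	-54	8
Posterior-medial	pos2	parieto-occipital sulcus (2)	Right	16	-61	26
Posterior-medial	pos3	parieto-occipital sulcus (3)	Right	14	-73	37
Posterior-medial	pos5	parieto-occipital sulcus (5)	Right	21	-66	20
Posterior-medial	PRECU1	Precuneus Gyrus (1)	Right	13	-53	14
Posterior-medial	PRECU7	Precuneus Gyrus (7)	Right	7	-63	36
Posterior-medial	PRECU8	Precuneus Gyrus (8)	Right	11	-68	41
Posterior-medial	PRECU9	Precuneus Gyrus (9)	Right	13	-68	50
Posterior-medial	T3_3	Inferior Temporal Gyrus (3)	Right	57	-46	-14
Posterior-medial	T3_4	Inferior Temporal Gyrus (4)	Right	54	-58	-11
Temporo-frontal	cing1	cingulate sulcus (1)	Right	7	27	31
Temporo-frontal	cing2	cingulate sulcus (2)	Right	8	13	47
Temporo-frontal	CINGa2	Anterior Cingulate Gyrus (2)	Right	7	33	23
Temporo-frontal	F3O1	Inferior Frontal Gyrus: Pars Orbitalis (1)	Right	44	33	-14
Temporo-frontal	F3t	Inferior Frontal Gyrus: Pars Triangularis (1)	Right	50	29	5
Temporo-frontal	INSa2	Anterior Insula Gyrus (2)	Right	35	18	-13
Temporo-frontal	INSa3	Anterior Insula Gyrus (3)	Right	37	24	0
Temporo-frontal	INSa4	Anterior Insula Gyrus (4)	Right	41	15	4
Temporo-frontal	O2_3	Middle Occipital Gyrus (3)	Right	45	-63	15
Temporo-frontal	PALL	Pallidum (1)	Left	-19	-8	-1
Temporo-frontal	PUT3	Putamen (3)	Left	-28	-6	2
Temporo-frontal	SMA2	Supplementary Motor Area (2)	Right	11	18	63
Temporo-frontal	SMA3	Supplementary Motor Area (3)	Right	6	10	66
Temporo-frontal	STS3	superior temporal sulcus (3)	Right	53	-32	0
Temporo-frontal	STS4	superior temporal sulcus (4)	Right	55	-46	15
Temporo-frontal	T1_4	Superior Temporal Gyrus (4)	Left	-59	-23	4
Temporo-frontal	T2_3	Middle Temporal Gyrus (3)	Right	62	-31	-5
Temporo-frontal	T2_4	Middle Temporal Gyrus (4)	Right	57	-53	3
Temporo-frontal	T3_5	Inferior Temporal Gyrus (5)	Right	49	-58	4
Temporo-frontal	THA1	Thalamus (1)	Left	-4	0	1
Parieto-frontal	f1_2	superior frontal sulcus (2)	Right	28	56	7
Parieto-frontal	f2_1	inferior frontal sulcus (1)	Right	46	40	10
Parieto-frontal	f2_2	inferior frontal sulcus (2)	Right	44	19	28
Parieto-frontal	F1M3	Medial Superior Frontal Gyrus (3)	Right	6	33	45
Parieto-frontal	F2_1	Middle Frontal Gyrus Gyrus (1)	Right	41	44	13
Parieto-frontal	F2_5	Middle Frontal Gyrus Gyrus (5)	Right	42	17	41
Parieto-frontal	F2O1	Middle Orbito-Frontal Gyrus (1)	Right	36	57	-6
Parieto-frontal	F2O2	Middle Orbito-Frontal Gyrus (2)	Right	40	50	-4
Parieto-frontal	ips2	intraparietal sulcus (2)	Right	37	-52	48
Parieto-frontal	orb1	orbital sulcus (1)	Right	26	41	-15
Parieto-frontal	P2	Inferior Parietal Gyrus (1)	Right	43	-53	48
Parieto-frontal	prec1	precentral sulcus (1)	Right	50	10	24
Parieto-frontal	prec4	precentral sulcus (4)	Right	44	1	48
Parieto-frontal	SMA1	Supplementary Motor Area Gyrus (1)	Right	6	21	49
Parieto-frontal	SMG6	Supramarginal Gyrus (6)	Right	54	-38	44
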