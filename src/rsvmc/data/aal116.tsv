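index	name	full_name	lobe	cerebellum
1	PreCG.L	Precentral gyrus, left	frontal	0
2	PreCG.R	Precentral gyrus, right	frontal	0
3	SFGdor.L	Superior frontal gyrus, dorsolateral, left	frontal	0
4	SFGdor.R	Superior frontal gyrus, dorsolateral, right	frontal	0
5	ORBsup.L	Superior frontal gyrus, orbital part, left	frontal	0
6	ORBsup.R	Superior frontal gyrus, orbital part, right	frontal	0
7	MFG.L	Middle frontal gyrus, left	frontal	0
8	MFG.R	Middle frontal gyrus, right	frontal	0
9	ORBmid.L	Middle frontal gyrus, orbital part, left	frontal	0
10	ORBmid.R	Middle frontal gyrus, orbital part, right	frontal	0
11	IFGoperc.L	Inferior frontal gyrus, opercular part, left	frontal	0
12	IFGoperc.R	Inferior frontal gyrus, opercular part, right	frontal	0
13	IFGtriang.L	Inferior frontal gyrus, triangular part, left	frontal	0
14	IFGtriang.R	Inferior frontal gyrus, triangular part, right	frontal	0
15	ORBinf.L	Inferior frontal gyrus, orbital part, left	frontal	0
16	ORBinf.R	Inferior frontal gyrus, orbital part, right	frontal	0
17	ROL.L	Rolandic operculum, left	frontal	0
18	ROL.R	Rolandic operculum, right	frontal	0
19	SMA.L	Supplementary motor area, left	frontal	0
20	SMA.R	Supplementary motor area, right	frontal	0
21	OLF.L	Olfactory cortex, left	frontal	0
22	OLF.R	Olfactory cortex, right	frontal	0
23	SFGmed.L	Superior frontal gyrus, medial, left	frontal	0
24	SFGmed.R	Superior frontal gyrus, medial, right	frontal	0
25	ORBsupmed.L	Superior frontal gyrus, medial orbital, left	frontal	0
26	ORBsupmed.R	Superior frontal gyrus, medial orbital, right	frontal	0
27	REC.L	Gyrus rectus, left	frontal	0
28	REC.R	Gyrus rectus, right	frontal	0
29	INS.L	Insula, left	insula	0
30	INS.R	Insula, right	insula	0
31	ACG.L	Anterior cingulate and paracingulate gyri, left	limbic	0
32	ACG.R	Anterior cingulate and paracingulate gyri, right	limbic	0
33	DCG.L	Median cingulate and paracingulate gyri, left	limbic	0
34	DCG.R	Median cingulate and paracingulate gyri, right	limbic	0
35	PCG.L	Posterior cingulate gyrus, left	limbic	0
36	PCG.R	Posterior cingulate gyrus, right	limbic	0
37	HIP.L	Hippocampus, left	limbic	0
38	HIP.R	Hippocampus, right	limbic	0
39	PHG.L	Parahippocampal gyrus, left	limbic	0
40	PHG.R	Parahippocampal gyrus, right	limbic	0
41	AMYG.L	Amygdala, left	limbic	0
42	AMYG.R	Amygdala, right	limbic	0
43	CAL.L	Calcarine fissure and surrounding cortex, left	occipital	0
44	CAL.R	Calcarine fissure and surrounding cortex, right	occipital	0
45	CUN.L	Cuneus, left	occipital	0
46	CUN.R	Cuneus, right	occipital	0
47	LING.L	Lingual gyrus, left	occipital	0
48	LING.R	Lingual gyrus, right	occipital	0
49	SOG.L	Superior occipital gyrus, left	occipital	0
50	SOG.R	Superior occipital gyrus, right	occipital	0
51	MOG.L	Middle occipital gyrus, left	occipital	0
52	MOG.R	Middle occipital gyrus, right	occipital	0
53	IOG.L	Inferior occipital gyrus, left	occipital	0
54	IOG.R	Inferior occipital gyrus, right	occipital	0
55	FFG.L	Fusiform gyrus, left	occipital	0
56	FFG.R	Fusiform gyrus, right	occipital	0
57	PoCG.L	Postcentral gyrus, left	parietal	0
58	PoCG.R	Postcentral gyrus, right	parietal	0
59	SPG.L	Superior parietal gyrus, left	parietal	0
60	SPG.R	Superior parietal gyrus, right	parietal	0
61	IPL.L	Inferior parietal, supramarginal and angular gyri, left	parietal	0
62	IPL.R	Inferior parietal, supramarginal and angular gyri, right	parietal	0
63	SMG.L	Supramarginal gyrus, left	parietal	0
64	SMG.R	Supramarginal gyrus, right	parietal	0
65	ANG.L	Angular gyrus, left	parietal	0
66	ANG.R	Angular gyrus, right	parietal	0
67	PCUN.L	Precuneus, left	parietal	0
68	PCUN.R	Precuneus, right	parietal	0
69	PCL.L	Paracentral lobule, left	parietal	0
70	PCL.R	Paracentral lobule, right	parietal	0
71	CAU.L	Caudate nucleus, left	subcortical	0
72	CAU.R	Caudate nucleus, right	subcortical	0
73	PUT.L	Lenticular nucleus, putamen, left	subcortical	0
74	PUT.R	Lenticular nucleus, putamen, right	subcortical	0
75	PAL.L	Lenticular nucleus, pallidum, left	subcortical	0
76	PAL.R	Lenticular nucleus, pallidum, right	subcortical	0
77	THA.L	Thalamus, left	subcortical	0
78	THA.R	Thalamus, right	subcortical	0
79	HES.L	Heschl gyrus, left	temporal	0
80	HES.R	Heschl gyrus, right	temporal	0
81	STG.L	Superior temporal gyrus, left	temporal	0
82	STG.R	Superior temporal gyrus, right	temporal	0
83	TPOsup.L	Temporal pole: superior temporal gyrus, left	temporal	0
84	TPOsup.R	Temporal pole: superior temporal gyrus, right	temporal	0
85	MTG.L	Middle temporal gyrus, left	temporal	0
86	MTG.R	Middle temporal gyrus, right	temporal	0
87	TPOmid.L	Temporal pole: middle temporal gyrus, left	temporal	0
88	TPOmid.R	Temporal pole: middle temporal gyrus, right	temporal	0
89	ITG.L	Inferior temporal gyrus, left	temporal	0
90	ITG.R	Inferior temporal gyrus, right	temporal	0
91	CRBLCrus1.L	Cerebellum, crus I, left	cerebellum	1
92	CRBLCrus1.R	Cerebellum, crus I, right	cerebellum	1
93	CRBLCrus2.L	Cerebellum, crus II, left	cerebellum	1
94	CRBLCrus2.R	Cerebellum, crus II, right	cerebellum	1
95	CRBL3.L	Cerebellum, lobule III, left	cerebellum	1
96	CRBL3.R	Cerebellum, lobule III, right	cerebellum	1
97	CRBL45.L	Cerebellum, lobules IV-V, left	cerebellum	1
98	CRBL45.R	Cerebellum, lobules IV-V, right	cerebellum	1
99	CRBL6.L	Cerebellum, lobule VI, left	cerebellum	1
100	CRBL6.R	Cerebellum, lobule VI, right	cerebellum	1
101	CRBL7b.L	Cerebellum, lobule VIIb, left	cerebellum	1
102	CRBL7b.R	Cerebellum, lobule VIIb, right	cerebellum	1
103	CRBL8.L	Cerebellum, lobule VIII, left	cerebellum	1
104	CRBL8.R	Cerebellum, lobule VIII, right	cerebellum	1
105	CRBL9.L	Cerebellum, lobule IX, left	cerebellum	1
106	CRBL9.R	Cerebellum, lobule IX, right	cerebellum	1
107	CRBL10.L	Cerebellum, lobule X, left	cerebellum	1
108	CRBL10.R	Cerebellum, lobule X, right	cerebellum	1
109	Vermis12	Cerebellar vermis I-II	cerebellum	1
110	Vermis3	Cerebellar vermis 3	cerebellum	1
111	Vermis45	Cerebellar vermis IV-V	cerebellum	1
112	Vermis6	Cerebellar vermis 6	cerebellum	1
113	Vermis7	Cerebellar vermis 7	cerebellum	1
114	Vermis8	Cerebellar vermis 8	cerebellum	1
115	Vermis9	Cerebellar vermis 9	cerebellum	1
116	Vermis10	Cerebellar vermis 10	cerebellum	1
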