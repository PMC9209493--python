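id	name	hemisphere	set
1	Left-Cerebral-White-Matter	left	WM45
2	Right-Cerebral-White-Matter	right	WM45
3	Left-Cerebellum-White-Matter	left	WM45
4	Right-Cerebellum-White-Matter	right	WM45
5	Brain-Stem	none	WM45
6	wm-lh-entorhinal	left	WM45
7	wm-rh-entorhinal	right	WM45
8	wm-lh-fusiform	left	WM45
9	wm-rh-fusiform	right	WM45
10	wm-lh-inferiorparietal	left	WM45
11	wm-rh-inferiorparietal	right	WM45
12	wm-lh-inferiortemporal	left	WM45
13	wm-rh-inferiortemporal	right	WM45
14	wm-lh-middletemporal	left	WM45
15	wm-rh-middletemporal	right	WM45
16	wm-lh-parahippocampal	left	WM45
17	wm-rh-parahippocampal	right	WM45
18	wm-lh-postcentral	left	WM45
19	wm-rh-postcentral	right	WM45
20	wm-lh-precentral	left	WM45
21	wm-rh-precentral	right	WM45
22	wm-lh-precuneus	left	WM45
23	wm-rh-precuneus	right	WM45
24	wm-lh-rostralmiddlefrontal	left	WM45
25	wm-rh-rostralmiddlefrontal	right	WM45
26	wm-lh-superiorfrontal	left	WM45
27	wm-rh-superiorfrontal	right	WM45
28	wm-lh-superiorparietal	left	WM45
29	wm-rh-superiorparietal	right	WM45
30	wm-lh-superiortemporal	left	WM45
31	wm-rh-superiortemporal	right	WM45
32	wm-lh-supramarginal	left	WM45
33	wm-rh-supramarginal	right	WM45
34	wm-lh-temporalpole	left	WM45
35	wm-rh-temporalpole	right	WM45
36	wm-lh-insula	left	WM45
37	wm-rh-insula	right	WM45
38	wm-lh-lateraloccipital	left	WM45
39	wm-rh-lateraloccipital	right	WM45
40	wm-lh-lingual	left	WM45
41	wm-rh-lingual	right	WM45
42	wm-lh-cuneus	left	WM45
43	wm-rh-cuneus	right	WM45
44	wm-lh-paracentral	left	WM45
45	wm-rh-paracentral	right	WM45
46	ctx-lh-bankssts	left	CTX70
47	ctx-rh-bankssts	right	CTX70
48	ctx-lh-caudalanteriorcingulate	left	CTX70
49	ctx-rh-caudalanteriorcingulate	right	CTX70
50	ctx-lh-caudalmiddlefrontal	left	CTX70
51	ctx-rh-caudalmiddlefrontal	right	CTX70
52	ctx-lh-cuneus	left	CTX70
53	ctx-rh-cuneus	right	CTX70
54	ctx-lh-entorhinal	left	CTX70
55	ctx-rh-entorhinal	right	CTX70
56	ctx-lh-fusiform	left	CTX70
57	ctx-rh-fusiform	right	CTX70
58	ctx-lh-inferiorparietal	left	CTX70
59	ctx-rh-inferiorparietal	right	CTX70
60	ctx-lh-inferiortemporal	left	CTX70
61	ctx-rh-inferiortemporal	right	CTX70
62	ctx-lh-isthmuscingulate	left	CTX70
63	ctx-rh-isthmuscingulate	right	CTX70
64	ctx-lh-lateraloccipital	left	CTX70
65	ctx-rh-lateraloccipital	right	CTX70
66	ctx-lh-lateralorbitofrontal	left	CTX70
67	ctx-rh-lateralorbitofrontal	right	CTX70
68	ctx-lh-lingual	left	CTX70
69	ctx-rh-lingual	right	CTX70
70	ctx-lh-medialorbitofrontal	left	CTX70
71	ctx-rh-medialorbitofrontal	right	CTX70
72	ctx-lh-middletemporal	left	CTX70
73	ctx-rh-middletemporal	right	CTX70
74	ctx-lh-parahippocampal	left	CTX70
75	ctx-rh-parahippocampal	right	CTX70
76	ctx-lh-paracentral	left	CTX70
77	ctx-rh-paracentral	right	CTX70
78	ctx-lh-parsopercularis	left	CTX70
79	ctx-rh-parsopercularis	right	CTX70
80	ctx-lh-parsorbitalis	left	CTX70
81	ctx-rh-parsorbitalis	right	CTX70
82	ctx-lh-parstriangularis	left	CTX70
83	ctx-rh-parstriangularis	right	CTX70
84	ctx-lh-pericalcarine	left	CTX70
85	ctx-rh-pericalcarine	right	CTX70
86	ctx-lh-postcentral	left	CTX70
87	ctx-rh-postcentral	right	CTX70
88	ctx-lh-posteriorcingulate	left	CTX70
89	ctx-rh-posteriorcingulate	right	CTX70
90	ctx-lh-precentral	left	CTX70
91	ctx-rh-precentral	right	CTX70
92	ctx-lh-precuneus	left	CTX70
93	ctx-rh-precuneus	right	CTX70
94	ctx-lh-rostralanteriorcingulate	left	CTX70
95	ctx-rh-rostralanteriorcingulate	right	CTX70
96	ctx-lh-rostralmiddlefrontal	left	CTX70
97	ctx-rh-rostralmiddlefrontal	right	CTX70
98	ctx-lh-superiorfrontal	left	CTX70
99	ctx-rh-superiorfrontal	right	CTX70
100	ctx-lh-superiorparietal	left	CTX70
101	ctx-rh-superiorparietal	right	CTX70
102	ctx-lh-superiortemporal	left	CTX70
103	ctx-rh-superiortemporal	right	CTX70
104	ctx-lh-supramarginal	left	CTX70
105	ctx-rh-supramarginal	right	CTX70
106	ctx-lh-temporalpole	left	CTX70
107	ctx-rh-temporalpole	right	CTX70
108	ctx-lh-transversetemporal	left	CTX70
109	ctx-rh-transversetemporal	right	CTX70
110	ctx-lh-insula	left	CTX70
111	ctx-rh-insula	right	CTX70
112	ctx-lh-frontalpole	left	CTX70
113	ctx-rh-frontalpole	right	CTX70
114	ctx-lh-hippocampus	left	CTX70
115	ctx-rh-hippocampus	right	CTX70
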