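region_id	label	hemisphere	homologue_id
0	lh_bankssts	left	41
1	lh_caudalanteriorcingulate	left	42
2	lh_caudalmiddlefrontal	left	43
3	lh_cuneus	left	44
4	lh_entorhinal	left	45
5	lh_fusiform	left	46
6	lh_inferiorparietal	left	47
7	lh_inferiortemporal	left	48
8	lh_isthmuscingulate	left	49
9	lh_lateraloccipital	left	50
10	lh_lateralorbitofrontal	left	51
11	lh_lingual	left	52
12	lh_medialorbitofrontal	left	53
13	lh_middletemporal	left	54
14	lh_parahippocampal	left	55
15	lh_paracentral	left	56
16	lh_parsopercularis	left	57
17	lh_parsorbitalis	left	58
18	lh_parstriangularis	left	59
19	lh_pericalcarine	left	60
20	lh_postcentral	left	61
21	lh_posteriorcingulate	left	62
22	lh_precentral	left	63
23	lh_precuneus	left	64
24	lh_rostralanteriorcingulate	left	65
25	lh_rostralmiddlefrontal	left	66
26	lh_superiorfrontal	left	67
27	lh_superiorparietal	left	68
28	lh_superiortemporal	left	69
29	lh_supramarginal	left	70
30	lh_frontalpole	left	71
31	lh_temporalpole	left	72
32	lh_transversetemporal	left	73
33	lh_insula	left	74
34	Left-Thalamus-Proper	left	75
35	Left-Caudate	left	76
36	Left-Putamen	left	77
37	Left-Pallidum	left	78
38	Left-Hippocampus	left	79
39	Left-Amygdala	left	80
40	Left-Accumbens-area	left	81
41	rh_bankssts	right	0
42	rh_caudalanteriorcingulate	right	1
43	rh_caudalmiddlefrontal	right	2
44	rh_cuneus	right	3
45	rh_entorhinal	right	4
46	rh_fusiform	right	5
47	rh_inferiorparietal	right	6
48	rh_inferiortemporal	right	7
49	rh_isthmuscingulate	right	8
50	rh_lateraloccipital	right	9
51	rh_lateralorbitofrontal	right	10
52	rh_lingual	right	11
53	rh_medialorbitofrontal	right	12
54	rh_middletemporal	right	13
55	rh_parahippocampal	right	14
56	rh_paracentral	right	15
57	rh_parsopercularis	right	16
58	rh_parsorbitalis	right	17
59	rh_parstriangularis	right	18
60	rh_pericalcarine	right	19
61	rh_postcentral	right	20
62	rh_posteriorcingulate	right	21
63	rh_precentral	right	22
64	rh_precuneus	right	23
65	rh_rostralanteriorcingulate	right	24
66	rh_rostralmiddlefrontal	right	25
67	rh_superiorfrontal	right	26
68	rh_superiorparietal	right	27
69	rh_superiortemporal	right	28
70	rh_supramarginal	right	29
71	rh_frontalpole	right	30
72	rh_temporalpole	right	31
73	rh_transversetemporal	right	32
74	rh_insula	right	33
75	Right-Thalamus-Proper	right	34
76	Right-Caudate	right	35
77	Right-Putamen	right	36
78	Right-Pallidum	right	37
79	Right-Hippocampus	right	38
80	Right-Amygdala	right	39
81	Right-Accumbens-area	right	40
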