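region_id,name,hemisphere,is_cortical
0,lh-bankssts,left,1
1,lh-caudalanteriorcingulate,left,1
2,lh-caudalmiddlefrontal,left,1
3,lh-cuneus,left,1
4,lh-entorhinal,left,1
5,lh-frontalpole,left,1
6,lh-fusiform,left,1
7,lh-inferiorparietal,left,1
8,lh-inferiortemporal,left,1
9,lh-insula,left,1
10,lh-isthmuscingulate,left,1
11,lh-lateraloccipital,left,1
12,lh-lateralorbitofrontal,left,1
13,lh-lingual,left,1
14,lh-medialorbitofrontal,left,1
15,lh-middletemporal,left,1
16,lh-paracentral,left,1
17,lh-parahippocampal,left,1
18,lh-parsopercularis,left,1
19,lh-parsorbitalis,left,1
20,lh-parstriangularis,left,1
21,lh-pericalcarine,left,1
22,lh-postcentral,left,1
23,lh-posteriorcingulate,left,1
24,lh-precentral,left,1
25,lh-precuneus,left,1
26,lh-rostralanteriorcingulate,left,1
27,lh-rostralmiddlefrontal,left,1
28,lh-superiorfrontal,left,1
29,lh-superiorparietal,left,1
30,lh-superiortemporal,left,1
31,lh-supramarginal,left,1
32,lh-transversetemporal,left,1
33,lh-thalamus,left,0
34,lh-caudate,left,0
35,lh-putamen,left,0
36,lh-pallidum,left,0
37,lh-hippocampus,left,0
38,lh-amygdala,left,0
39,lh-accumbens,left,0
40,lh-ventraldc,left,0
41,rh-bankssts,right,1
42,rh-caudalanteriorcingulate,right,1
43,rh-caudalmiddlefrontal,right,1
44,rh-cuneus,right,1
45,rh-entorhinal,right,1
46,rh-frontalpole,right,1
47,rh-fusiform,right,1
48,rh-inferiorparietal,right,1
49,rh-inferiortemporal,right,1
50,rh-insula,right,1
51,rh-isthmuscingulate,right,1
52,rh-lateraloccipital,right,1
53,rh-lateralorbitofrontal,right,1
54,rh-lingual,right,1
55,rh-medialorbitofrontal,right,1
56,rh-middletemporal,right,1
57,rh-paracentral,right,1
58,rh-parahippocampal,right,1
59,rh-parsopercularis,right,1
60,rh-parsorbitalis,right,1
61,rh-parstriangularis,right,1
62,rh-pericalcarine,right,1
63,rh-postcentral,right,1
64,rh-posteriorcingulate,right,1
65,rh-precentral,right,1
66,rh-precuneus,right,1
67,rh-rostralanteriorcingulate,right,1
68,rh-rostralmiddlefrontal,right,1
69,rh-superiorfrontal,right,1
70,rh-superiorparietal,right,1
71,rh-superiortemporal,right,1
72,rh-supramarginal,right,1
73,rh-transversetemporal,right,1
74,rh-thalamus,right,0
75,rh-caudate,right,0
76,rh-putamen,right,0
77,rh-pallidum,right,0
78,rh-hippocampus,right,0
79,rh-amygdala,right,0
80,rh-accumbens,right,0
81,rh-ventraldc,right,0
82,brainstem,midline,0
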