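roi_id,abbreviation,name,hemisphere
1,PreCG.L,"Precentral gyrus (left)",L
2,PreCG.R,"Precentral gyrus (right)",R
3,SFGdor.L,"Superior frontal gyrus, dorsolateral (left)",L
4,SFGdor.R,"Superior frontal gyrus, dorsolateral (right)",R
5,ORBsup.L,"Superior frontal gyrus, orbital part (left)",L
6,ORBsup.R,"Superior frontal gyrus, orbital part (right)",R
7,MFG.L,"Middle frontal gyrus (left)",L
8,MFG.R,"Middle frontal gyrus (right)",R
9,ORBmid.L,"Middle frontal gyrus, orbital part (left)",L
10,ORBmid.R,"Middle frontal gyrus, orbital part (right)",R
11,IFGoperc.L,"Inferior frontal gyrus, opercular part (left)",L
12,IFGoperc.R,"Inferior frontal gyrus, opercular part (right)",R
13,IFGtriang.L,"Inferior frontal gyrus, triangular part (left)",L
14,IFGtriang.R,"Inferior frontal gyrus, triangular part (right)",R
15,ORBinf.L,"Inferior frontal gyrus, orbital part (left)",L
16,ORBinf.R,"Inferior frontal gyrus, orbital part (right)",R
17,ROL.L,"Rolandic operculum (left)",L
18,ROL.R,"Rolandic operculum (right)",R
19,SMA.L,"Supplementary motor area (left)",L
20,SMA.R,"Supplementary motor area (right)",R
21,OLF.L,"Olfactory cortex (left)",L
22,OLF.R,"Olfactory cortex (right)",R
23,SFGmed.L,"Superior frontal gyrus, medial (left)",L
24,SFGmed.R,"Superior frontal gyrus, medial (right)",R
25,ORBsupmed.L,"Superior frontal gyrus, medial orbital (left)",L
26,ORBsupmed.R,"Superior frontal gyrus, medial orbital (right)",R
27,REC.L,"Gyrus rectus (left)",L
28,REC.R,"Gyrus rectus (right)",R
29,INS.L,"Insula (left)",L
30,INS.R,"Insula (right)",R
31,ACG.L,"Anterior cingulate and paracingulate gyri (left)",L
32,ACG.R,"Anterior cingulate and paracingulate gyri (right)",R
33,DCG.L,"Median cingulate and paracingulate gyri (left)",L
34,DCG.R,"Median cingulate and paracingulate gyri (right)",R
35,PCG.L,"Posterior cingulate gyrus (left)",L
36,PCG.R,"Posterior cingulate gyrus (right)",R
37,HIP.L,"Hippocampus (left)",L
38,HIP.R,"Hippocampus (right)",R
39,PHG.L,"Parahippocampal gyrus (left)",L
40,PHG.R,"Parahippocampal gyrus (right)",R
41,AMYG.L,"Amygdala (left)",L
42,AMYG.R,"Amygdala (right)",R
43,CAL.L,"Calcarine fissure and surrounding cortex (left)",L
44,CAL.R,"Calcarine fissure and surrounding cortex (right)",R
45,CUN.L,"Cuneus (left)",L
46,CUN.R,"Cuneus (right)",R
47,LING.L,"Lingual gyrus (left)",L
48,LING.R,"Lingual gyrus (right)",R
49,SOG.L,"Superior occipital gyrus (left)",L
50,SOG.R,"Superior occipital gyrus (right)",R
51,MOG.L,"Middle occipital gyrus (left)",L
52,MOG.R,"Middle occipital gyrus (right)",R
53,IOG.L,"Inferior occipital gyrus (left)",L
54,IOG.R,"Inferior occipital gyrus (right)",R
55,FFG.L,"Fusiform gyrus (left)",L
56,FFG.R,"Fusiform gyrus (right)",R
57,PoCG.L,"Postcentral gyrus (left)",L
58,PoCG.R,"Postcentral gyrus (right)",R
59,SPG.L,"Superior parietal gyrus (left)",L
60,SPG.R,"Superior parietal gyrus (right)",R
61,IPL.L,"Inferior parietal supramarginal and angular gyri (left)",L
62,IPL.R,"Inferior parietal supramarginal and angular gyri (right)",R
63,SMG.L,"Supramarginal gyrus (left)",L
64,SMG.R,"Supramarginal gyrus (right)",R
65,ANG.L,"Angular gyrus (left)",L
66,ANG.R,"Angular gyrus (right)",R
67,PCUN.L,"Precuneus (left)",L
68,PCUN.R,"Precuneus (right)",R
69,PCL.L,"Paracentral lobule (left)",L
70,PCL.R,"Paracentral lobule (right)",R
71,CAU.L,"Caudate nucleus (left)",L
72,CAU.R,"Caudate nucleus (right)",R
73,PUT.L,"Lenticular nucleus, putamen (left)",L
74,PUT.R,"Lenticular nucleus, putamen (right)",R
75,PAL.L,"Lenticular nucleus, pallidum (left)",L
76,PAL.R,"Lenticular nucleus, pallidum (right)",R
77,THA.L,"Thalamus (left)",L
78,THA.R,"Thalamus (right)",R
79,HES.L,"Heschl gyrus (left)",L
80,HES.R,"Heschl gyrus (right)",R
81,STG.L,"Superior temporal gyrus (left)",L
82,STG.R,"Superior temporal gyrus (right)",R
83,TPOsup.L,"Temporal pole: superior temporal gyrus (left)",L
84,TPOsup.R,"Temporal pole: superior temporal gyrus (right)",R
85,MTG.L,"Middle temporal gyrus (left)",L
86,MTG.R,"Middle temporal gyrus (right)",R
87,TPOmid.L,"Temporal pole: middle temporal gyrus (left)",L
88,TPOmid.R,"Temporal pole: middle temporal gyrus (right)",R
89,ITG.L,"Inferior temporal gyrus (left)",L
90,ITG.R,"Inferior temporal gyrus (right)",R
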