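roi_id,name,hemisphere,lobe
1,Precentral_L,L,motorstrip
2,Precentral_R,R,motorstrip
3,Frontal_Sup_L,L,prefrontal
4,Frontal_Sup_R,R,prefrontal
5,Frontal_Sup_Orb_L,L,prefrontal
6,Frontal_Sup_Orb_R,R,prefrontal
7,Frontal_Mid_L,L,prefrontal
8,Frontal_Mid_R,R,prefrontal
9,Frontal_Mid_Orb_L,L,prefrontal
10,Frontal_Mid_Orb_R,R,prefrontal
11,Frontal_Inf_Oper_L,L,prefrontal
12,Frontal_Inf_Oper_R,R,prefrontal
13,Frontal_Inf_Tri_L,L,prefrontal
14,Frontal_Inf_Tri_R,R,prefrontal
15,Frontal_Inf_Orb_L,L,prefrontal
16,Frontal_Inf_Orb_R,R,prefrontal
17,Rolandic_Oper_L,L,motorstrip
18,Rolandic_Oper_R,R,motorstrip
19,Supp_Motor_Area_L,L,motorstrip
20,Supp_Motor_Area_R,R,motorstrip
21,Olfactory_L,L,prefrontal
22,Olfactory_R,R,prefrontal
23,Frontal_Sup_Medial_L,L,prefrontal
24,Frontal_Sup_Medial_R,R,prefrontal
25,Frontal_Med_Orb_L,L,prefrontal
26,Frontal_Med_Orb_R,R,prefrontal
27,Rectus_L,L,prefrontal
28,Rectus_R,R,prefrontal
29,Insula_L,L,insula
30,Insula_R,R,insula
31,Cingulum_Ant_L,L,limbic
32,Cingulum_Ant_R,R,limbic
33,Cingulum_Mid_L,L,limbic
34,Cingulum_Mid_R,R,limbic
35,Cingulum_Post_L,L,limbic
36,Cingulum_Post_R,R,limbic
37,Hippocampus_L,L,limbic
38,Hippocampus_R,R,limbic
39,ParaHippocampal_L,L,limbic
40,ParaHippocampal_R,R,limbic
41,Amygdala_L,L,limbic
42,Amygdala_R,R,limbic
43,Calcarine_L,L,occipital
44,Calcarine_R,R,occipital
45,Cuneus_L,L,occipital
46,Cuneus_R,R,occipital
47,Lingual_L,L,occipital
48,Lingual_R,R,occipital
49,Occipital_Sup_L,L,occipital
50,Occipital_Sup_R,R,occipital
51,Occipital_Mid_L,L,occipital
52,Occipital_Mid_R,R,occipital
53,Occipital_Inf_L,L,occipital
54,Occipital_Inf_R,R,occipital
55,Fusiform_L,L,temporal
56,Fusiform_R,R,temporal
57,Postcentral_L,L,motorstrip
58,Postcentral_R,R,motorstrip
59,Parietal_Sup_L,L,parietal
60,Parietal_Sup_R,R,parietal
61,Parietal_Inf_L,L,parietal
62,Parietal_Inf_R,R,parietal
63,SupraMarginal_L,L,parietal
64,SupraMarginal_R,R,parietal
65,Angular_L,L,parietal
66,Angular_R,R,parietal
67,Precuneus_L,L,parietal
68,Precuneus_R,R,parietal
69,Paracentral_Lobule_L,L,motorstrip
70,Paracentral_Lobule_R,R,motorstrip
71,Caudate_L,L,subcortical
72,Caudate_R,R,subcortical
73,Putamen_L,L,subcortical
74,Putamen_R,R,subcortical
75,Pallidum_L,L,subcortical
76,Pallidum_R,R,subcortical
77,Thalamus_L,L,subcortical
78,Thalamus_R,R,subcortical
79,Heschl_L,L,temporal
80,Heschl_R,R,temporal
81,Temporal_Sup_L,L,temporal
82,Temporal_Sup_R,R,temporal
83,Temporal_Pole_Sup_L,L,temporal
84,Temporal_Pole_Sup_R,R,temporal
85,Temporal_Pole_Mid_L,L,temporal
86,Temporal_Pole_Mid_R,R,temporal
87,Temporal_Mid_L,L,temporal
88,Temporal_Mid_R,R,temporal
89,Temporal_Inf_L,L,temporal
90,Temporal_Inf_R,R,temporal
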