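region	hemisphere	dmn	limbic	visual
Precentral_L	L	0	0	0
Precentral_R	R	0	0	0
Frontal_Sup_L	L	1	0	0
Frontal_Sup_R	R	1	0	0
Frontal_Sup_Orb_L	L	1	0	0
Frontal_Sup_Orb_R	R	1	0	0
Frontal_Mid_L	L	1	0	0
Frontal_Mid_R	R	1	0	0
Frontal_Mid_Orb_L	L	1	0	0
Frontal_Mid_Orb_R	R	1	0	0
Frontal_Inf_Oper_L	L	1	0	0
Frontal_Inf_Oper_R	R	1	0	0
Frontal_Inf_Tri_L	L	1	0	0
Frontal_Inf_Tri_R	R	1	0	0
Frontal_Inf_Orb_L	L	1	0	0
Frontal_Inf_Orb_R	R	1	0	0
Rolandic_Oper_L	L	0	0	0
Rolandic_Oper_R	R	0	0	0
Supp_Motor_Area_L	L	0	0	0
Supp_Motor_Area_R	R	0	0	0
Olfactory_L	L	0	1	0
Olfactory_R	R	0	1	0
Frontal_Sup_Medial_L	L	0	0	0
Frontal_Sup_Medial_R	R	0	0	0
Frontal_Med_Orb_L	L	0	0	0
Frontal_Med_Orb_R	R	0	0	0
Rectus_L	L	0	0	0
Rectus_R	R	0	0	0
Insula_L	L	0	1	0
Insula_R	R	0	1	0
Cingulum_Ant_L	L	1	1	0
Cingulum_Ant_R	R	1	1	0
Cingulum_Mid_L	L	1	1	0
Cingulum_Mid_R	R	1	1	0
Cingulum_Post_L	L	1	1	0
Cingulum_Post_R	R	1	1	0
Hippocampus_L	L	1	1	0
Hippocampus_R	R	1	1	0
ParaHippocampal_L	L	1	1	0
ParaHippocampal_R	R	1	1	0
Amygdala_L	L	0	1	0
Amygdala_R	R	0	1	0
Calcarine_L	L	0	0	1
Calcarine_R	R	0	0	1
Cuneus_L	L	0	0	1
Cuneus_R	R	0	0	1
Lingual_L	L	0	0	1
Lingual_R	R	0	0	1
Occipital_Sup_L	L	0	0	1
Occipital_Sup_R	R	0	0	1
Occipital_Mid_L	L	1	0	1
Occipital_Mid_R	R	1	0	1
Occipital_Inf_L	L	0	0	1
Occipital_Inf_R	R	0	0	1
Fusiform_L	L	0	0	1
Fusiform_R	R	0	0	1
Postcentral_L	L	0	0	0
Postcentral_R	R	0	0	0
Parietal_Sup_L	L	0	0	0
Parietal_Sup_R	R	0	0	0
Parietal_Inf_L	L	0	0	0
Parietal_Inf_R	R	0	0	0
SupraMarginal_L	L	0	0	0
SupraMarginal_R	R	0	0	0
Angular_L	L	1	0	0
Angular_R	R	1	0	0
Precuneus_L	L	1	0	0
Precuneus_R	R	1	0	0
Paracentral_Lobule_L	L	0	0	0
Paracentral_Lobule_R	R	0	0	0
Caudate_L	L	0	0	0
Caudate_R	R	0	0	0
Putamen_L	L	0	0	0
Putamen_R	R	0	0	0
Pallidum_L	L	0	0	0
Pallidum_R	R	0	0	0
Thalamus_L	L	1	0	0
Thalamus_R	R	1	0	0
Heschl_L	L	0	0	0
Heschl_R	R	0	0	0
Temporal_Sup_L	L	0	0	0
Temporal_Sup_R	R	0	0	0
Temporal_Pole_Sup_L	L	0	0	0
Temporal_Pole_Sup_R	R	0	0	0
Temporal_Mid_L	L	0	0	0
Temporal_Mid_R	R	0	0	0
Temporal_Pole_Mid_L	L	0	0	0
Temporal_Pole_Mid_R	R	0	0	0
Temporal_Inf_L	L	0	0	1
Temporal_Inf_R	R	0	0	1
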