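label	x	y	z	location_group
Precentral_L	-39	-6	51	Precentral Gyrus
Precentral_R	39	-6	51	Precentral Gyrus
Frontal_Sup_L	-21	31	44	Superior Frontal Gyrus
Frontal_Sup_R	21	31	44	Superior Frontal Gyrus
Frontal_Sup_Orb_L	-17	47	-13	Orbitofrontal Cortex
Frontal_Sup_Orb_R	17	47	-13	Orbitofrontal Cortex
Frontal_Mid_L	-34	33	33	Middle Frontal Gyrus
Frontal_Mid_R	34	33	33	Middle Frontal Gyrus
Frontal_Mid_Orb_L	-31	50	-10	Orbitofrontal Cortex
Frontal_Mid_Orb_R	31	50	-10	Orbitofrontal Cortex
Frontal_Inf_Oper_L	-49	15	21	Inferior Frontal Gyrus
Frontal_Inf_Oper_R	49	15	21	Inferior Frontal Gyrus
Frontal_Inf_Tri_L	-47	30	14	Inferior Frontal Gyrus
Frontal_Inf_Tri_R	47	30	14	Inferior Frontal Gyrus
Frontal_Inf_Orb_L	-37	31	-12	Orbitofrontal Cortex
Frontal_Inf_Orb_R	37	31	-12	Orbitofrontal Cortex
Rolandic_Oper_L	-49	-8	14	Postcentral Gyrus
Rolandic_Oper_R	49	-8	14	Postcentral Gyrus
Supp_Motor_Area_L	-6	5	61	Superior Frontal Gyrus
Supp_Motor_Area_R	6	5	61	Superior Frontal Gyrus
Olfactory_L	-9	15	-12	Orbitofrontal Cortex
Olfactory_R	9	15	-12	Orbitofrontal Cortex
Frontal_Sup_Medial_L	-6	49	31	Superior Frontal Gyrus
Frontal_Sup_Medial_R	6	49	31	Superior Frontal Gyrus
Frontal_Med_Orb_L	-6	52	-7	Orbitofrontal Cortex
Frontal_Med_Orb_R	6	52	-7	Orbitofrontal Cortex
Rectus_L	-6	37	-18	Orbitofrontal Cortex
Rectus_R	6	37	-18	Orbitofrontal Cortex
Insula_L	-37	7	3	Insula
Insula_R	37	7	3	Insula
Cingulum_Ant_L	-5	35	14	Cingulate Gyrus
Cingulum_Ant_R	5	35	14	Cingulate Gyrus
Cingulum_Mid_L	-6	-15	42	Cingulate Gyrus
Cingulum_Mid_R	6	-15	42	Cingulate Gyrus
Cingulum_Post_L	-6	-43	25	Cingulate Gyrus
Cingulum_Post_R	6	-43	25	Cingulate Gyrus
Hippocampus_L	-27	-21	-10	Hippocampus
Hippocampus_R	27	-21	-10	Hippocampus
ParaHippocampal_L	-24	-16	-21	Hippocampus
ParaHippocampal_R	24	-16	-21	Hippocampus
Amygdala_L	-25	-1	-18	Amygdala
Amygdala_R	25	-1	-18	Amygdala
Calcarine_L	-9	-79	6	Occipital Lobe
Calcarine_R	9	-79	6	Occipital Lobe
Cuneus_L	-8	-80	27	Occipital Lobe
Cuneus_R	8	-80	27	Occipital Lobe
Lingual_L	-15	-68	-5	Occipital Lobe
Lingual_R	15	-68	-5	Occipital Lobe
Occipital_Sup_L	-19	-84	28	Occipital Lobe
Occipital_Sup_R	19	-84	28	Occipital Lobe
Occipital_Mid_L	-33	-81	16	Occipital Lobe
Occipital_Mid_R	33	-81	16	Occipital Lobe
Occipital_Inf_L	-38	-82	-8	Occipital Lobe
Occipital_Inf_R	38	-82	-8	Occipital Lobe
Fusiform_L	-32	-40	-20	Temporal Lobe
Fusiform_R	32	-40	-20	Temporal Lobe
Postcentral_L	-42	-23	49	Postcentral Gyrus
Postcentral_R	42	-23	49	Postcentral Gyrus
Parietal_Sup_L	-24	-60	59	Superior Parietal Lobe
Parietal_Sup_R	24	-60	59	Superior Parietal Lobe
Parietal_Inf_L	-43	-46	47	Inferior Parietal Lobe
Parietal_Inf_R	43	-46	47	Inferior Parietal Lobe
SupraMarginal_L	-56	-32	34	Inferior Parietal Lobe
SupraMarginal_R	56	-32	34	Inferior Parietal Lobe
Angular_L	-45	-60	39	Inferior Parietal Lobe
Angular_R	45	-60	39	Inferior Parietal Lobe
Precuneus_L	-7	-56	48	Superior Parietal Lobe
Precuneus_R	7	-56	48	Superior Parietal Lobe
Paracentral_Lobule_L	-7	-25	61	Precentral Gyrus
Paracentral_Lobule_R	7	-25	61	Precentral Gyrus
Caudate_L	-12	11	9	Basal Ganglia
Caudate_R	12	11	9	Basal Ganglia
Putamen_L	-25	4	2	Basal Ganglia
Putamen_R	25	4	2	Basal Ganglia
Pallidum_L	-19	0	0	Basal Ganglia
Pallidum_R	19	0	0	Basal Ganglia
Thalamus_L	-11	-18	8	Thalamus
Thalamus_R	11	-18	8	Thalamus
Heschl_L	-42	-19	10	Temporal Lobe
Heschl_R	42	-19	10	Temporal Lobe
Temporal_Sup_L	-55	-21	7	Temporal Lobe
Temporal_Sup_R	55	-21	7	Temporal Lobe
Temporal_Pole_Sup_L	-40	15	-20	Temporal Lobe
Temporal_Pole_Sup_R	40	15	-20	Temporal Lobe
Temporal_Mid_L	-54	-34	-2	Temporal Lobe
Temporal_Mid_R	54	-34	-2	Temporal Lobe
Temporal_Pole_Mid_L	-40	15	-32	Temporal Lobe
Temporal_Pole_Mid_R	40	15	-32	Temporal Lobe
Temporal_Inf_L	-50	-28	-23	Temporal Lobe
Temporal_Inf_R	50	-28	-23	Temporal Lobe
Cerebelum_Crus1_L	-35	-67	-29	Cerebellum
Cerebelum_Crus1_R	35	-67	-29	Cerebellum
Cerebelum_Crus2_L	-28	-74	-38	Cerebellum
Cerebelum_Crus2_R	28	-74	-38	Cerebellum
Cerebelum_3_L	-9	-37	-19	Cerebellum
Cerebelum_3_R	9	-37	-19	Cerebellum
Cerebelum_4_5_L	-15	-43	-17	Cerebellum
Cerebelum_4_5_R	15	-43	-17	Cerebellum
Cerebelum_6_L	-23	-59	-22	Cerebellum
Cerebelum_6_R	23	-59	-22	Cerebellum
Cerebelum_7b_L	-32	-60	-45	Cerebellum
Cerebelum_7b_R	32	-60	-45	Cerebellum
Cerebelum_8_L	-25	-55	-49	Cerebellum
Cerebelum_8_R	25	-55	-49	Cerebellum
Cerebelum_9_L	-11	-49	-46	Cerebellum
Cerebelum_9_R	11	-49	-46	Cerebellum
Cerebelum_10_L	-23	-34	-42	Cerebellum
Cerebelum_10_R	23	-34	-42	Cerebellum
Vermis_1_2	0	-39	-20	Cerebellum
Vermis_3	0	-40	-11	Cerebellum
Vermis_4_5	0	-52	-6	Cerebellum
Vermis_6	0	-67	-15	Cerebellum
Vermis_7	0	-72	-25	Cerebellum
Vermis_8	0	-64	-34	Cerebellum
Vermis_9	0	-55	-35	Cerebellum
Vermis_10	0	-46	-32	Cerebellum
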