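label	x	y	z	location_group
L_dorsal_granular_insula	-38	-6	5	Insula
R_dorsal_granular_insula	38	-6	5	Insula
L_ventral_agranular_insula	-34	12	-12	Insula
R_ventral_agranular_insula	34	12	-12	Insula
L_dorsal_agranular_insula	-36	14	2	Insula
R_dorsal_agranular_insula	36	14	2	Insula
L_dorsal_dysgranular_insula	-38	2	1	Insula
R_dorsal_dysgranular_insula	38	2	1	Insula
L_ventral_dysgranular_insula	-38	-2	-10	Insula
R_ventral_dysgranular_insula	38	-2	-10	Insula
L_posterior_insula	-40	-16	4	Insula
R_posterior_insula	40	-16	4	Insula
L_medial_amygdala	-18	-4	-18	Amygdala
R_medial_amygdala	18	-4	-18	Amygdala
L_lateral_amygdala	-28	-2	-22	Amygdala
R_lateral_amygdala	28	-2	-22	Amygdala
L_medial_prefrontal_thalamus	-6	-16	6	Thalamus
R_medial_prefrontal_thalamus	6	-16	6	Thalamus
L_premotor_thalamus	-12	-14	10	Thalamus
R_premotor_thalamus	12	-14	10	Thalamus
L_sensory_thalamus	-15	-22	4	Thalamus
R_sensory_thalamus	15	-22	4	Thalamus
L_caudal_temporal_thalamus	-12	-28	2	Thalamus
R_caudal_temporal_thalamus	12	-28	2	Thalamus
L_posterior_parietal_thalamus	-14	-26	12	Thalamus
R_posterior_parietal_thalamus	14	-26	12	Thalamus
L_posterior_midcingulate	-5	-18	40	Cingulate Gyrus
R_posterior_midcingulate	5	-18	40	Cingulate Gyrus
L_caudal_ventral_anterior_cingulate	-5	24	20	Cingulate Gyrus
R_caudal_ventral_anterior_cingulate	5	24	20	Cingulate Gyrus
L_rostroventral_ventral_anterior_cingulate	-5	38	2	Cingulate Gyrus
R_rostroventral_ventral_anterior_cingulate	5	38	2	Cingulate Gyrus
R_subgenual_dorsal_anterior_cingulate	5	28	-8	Cingulate Gyrus
R_caudal_ventral_posterior_cingulate	5	-40	22	Cingulate Gyrus
L_caudal_hippocampus	-26	-32	-8	Hippocampus
R_caudal_hippocampus	26	-32	-8	Hippocampus
L_rostral_hippocampus	-24	-14	-18	Hippocampus
R_rostral_hippocampus	24	-14	-18	Hippocampus
L_dorsolateral_putamen	-28	-4	4	Basal Ganglia
R_dorsolateral_putamen	28	-4	4	Basal Ganglia
L_ventromedial_putamen	-22	6	-6	Basal Ganglia
R_ventromedial_putamen	22	6	-6	Basal Ganglia
L_primary_somatosensory_trunk	-12	-38	66	Postcentral Gyrus
R_primary_somatosensory_trunk	12	-38	66	Postcentral Gyrus
L_primary_somatosensory_tongue	-52	-12	32	Postcentral Gyrus
R_primary_somatosensory_tongue	52	-12	32	Postcentral Gyrus
L_primary_somatosensory_larynx	-58	-8	24	Postcentral Gyrus
R_primary_somatosensory_larynx	58	-8	24	Postcentral Gyrus
L_primary_motor	-38	-20	54	Precentral Gyrus
R_primary_motor	38	-20	54	Precentral Gyrus
L_dorsolateral_periaqueductal_gray	-3	-30	-10	Brainstem
R_dorsolateral_periaqueductal_gray	3	-30	-10	Brainstem
R_lateral_periaqueductal_gray	5	-32	-12	Brainstem
R_ventrolateral_periaqueductal_gray	4	-34	-14	Brainstem
L_opercular_pars_triangularis	-50	18	12	Inferior Frontal Gyrus
R_opercular_pars_triangularis	50	18	12	Inferior Frontal Gyrus
L_ventral_pars_triangularis	-46	28	2	Inferior Frontal Gyrus
R_ventral_pars_triangularis	46	28	2	Inferior Frontal Gyrus
L_orbitofrontal	-24	42	-14	Orbitofrontal Cortex
R_orbitofrontal	24	42	-14	Orbitofrontal Cortex
L_medial_orbitofrontal	-8	46	-12	Orbitofrontal Cortex
R_medial_orbitofrontal	8	46	-12	Orbitofrontal Cortex
L_ventral_dorsolateral_prefrontal	-42	36	22	Middle Frontal Gyrus
R_ventrolateral_prefrontal	44	40	4	Middle Frontal Gyrus
L_dorsomedial_prefrontal	-6	40	40	Superior Frontal Gyrus
R_dorsomedial_prefrontal	6	40	40	Superior Frontal Gyrus
L_inferior_parietal	-48	-52	44	Inferior Parietal Lobe
R_inferior_parietal	48	-52	44	Inferior Parietal Lobe
L_supramarginal_pain	-58	-36	30	Inferior Parietal Lobe
R_supramarginal_pain	58	-36	30	Inferior Parietal Lobe
L_postcentral_somatosensory_association	-20	-48	62	Superior Parietal Lobe
R_postcentral_somatosensory_association	20	-48	62	Superior Parietal Lobe
L_secondary_visual	-12	-84	4	Occipital Lobe
R_secondary_visual	12	-84	4	Occipital Lobe
L_superior_temporal_pain	-54	-26	6	Temporal Lobe
R_superior_temporal_pain	54	-26	6	Temporal Lobe
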