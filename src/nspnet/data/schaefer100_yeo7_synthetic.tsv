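region_id	system_name
7Networks_LH_Vis_1	visual
7Networks_LH_Vis_2	visual
7Networks_LH_Vis_3	visual
7Networks_LH_Vis_4	visual
7Networks_LH_Vis_5	visual
7Networks_LH_Vis_6	visual
7Networks_LH_Vis_7	visual
7Networks_RH_Vis_1	visual
7Networks_RH_Vis_2	visual
7Networks_RH_Vis_3	visual
7Networks_RH_Vis_4	visual
7Networks_RH_Vis_5	visual
7Networks_RH_Vis_6	visual
7Networks_RH_Vis_7	visual
7Networks_LH_SomMot_1	motor
7Networks_LH_SomMot_2	motor
7Networks_LH_SomMot_3	motor
7Networks_LH_SomMot_4	motor
7Networks_LH_SomMot_5	motor
7Networks_LH_SomMot_6	motor
7Networks_LH_SomMot_7	motor
7Networks_RH_SomMot_1	motor
7Networks_RH_SomMot_2	motor
7Networks_RH_SomMot_3	motor
7Networks_RH_SomMot_4	motor
7Networks_RH_SomMot_5	motor
7Networks_RH_SomMot_6	motor
7Networks_RH_SomMot_7	motor
7Networks_LH_DorsAttn_1	dorsal_attention
7Networks_LH_DorsAttn_2	dorsal_attention
7Networks_LH_DorsAttn_3	dorsal_attention
7Networks_LH_DorsAttn_4	dorsal_attention
7Networks_LH_DorsAttn_5	dorsal_attention
7Networks_LH_DorsAttn_6	dorsal_attention
7Networks_LH_DorsAttn_7	dorsal_attention
7Networks_RH_DorsAttn_1	dorsal_attention
7Networks_RH_DorsAttn_2	dorsal_attention
7Networks_RH_DorsAttn_3	dorsal_attention
7Networks_RH_DorsAttn_4	dorsal_attention
7Networks_RH_DorsAttn_5	dorsal_attention
7Networks_RH_DorsAttn_6	dorsal_attention
7Networks_LH_SalVentAttn_1	salient_attention
7Networks_LH_SalVentAttn_2	salient_attention
7Networks_LH_SalVentAttn_3	salient_attention
7Networks_LH_SalVentAttn_4	salient_attention
7Networks_LH_SalVentAttn_5	salient_attention
7Networks_LH_SalVentAttn_6	salient_attention
7Networks_RH_SalVentAttn_1	salient_attention
7Networks_RH_SalVentAttn_2	salient_attention
7Networks_RH_SalVentAttn_3	salient_attention
7Networks_RH_SalVentAttn_4	salient_attention
7Networks_RH_SalVentAttn_5	salient_attention
7Networks_RH_SalVentAttn_6	salient_attention
7Networks_LH_Limbic_1	limbic
7Networks_LH_Limbic_2	limbic
7Networks_LH_Limbic_3	limbic
7Networks_LH_Limbic_4	limbic
7Networks_LH_Limbic_5	limbic
7Networks_RH_Limbic_1	limbic
7Networks_RH_Limbic_2	limbic
7Networks_RH_Limbic_3	limbic
7Networks_RH_Limbic_4	limbic
7Networks_RH_Limbic_5	limbic
7Networks_LH_Cont_1	control
7Networks_LH_Cont_2	control
7Networks_LH_Cont_3	control
7Networks_LH_Cont_4	control
7Networks_LH_Cont_5	control
7Networks_LH_Cont_6	control
7Networks_RH_Cont_1	control
7Networks_RH_Cont_2	control
7Networks_RH_Cont_3	control
7Networks_RH_Cont_4	control
7Networks_RH_Cont_5	control
7Networks_RH_Cont_6	control
7Networks_RH_Cont_7	control
7Networks_LH_Default_1	default
7Networks_LH_Default_2	default
7Networks_LH_Default_3	default
7Networks_LH_Default_4	default
7Networks_LH_Default_5	default
7Networks_LH_Default_6	default
7Networks_LH_Default_7	default
7Networks_LH_Default_8	default
7Networks_LH_Default_9	default
7Networks_LH_Default_10	default
7Networks_LH_Default_11	default
7Networks_LH_Default_12	default
7Networks_RH_Default_1	default
7Networks_RH_Default_2	default
7Networks_RH_Default_3	default
7Networks_RH_Default_4	default
7Networks_RH_Default_5	default
7Networks_RH_Default_6	default
7Networks_RH_Default_7	default
7Networks_RH_Default_8	default
7Networks_RH_Default_9	default
7Networks_RH_Default_10	default
7Networks_RH_Default_11	default
7Networks_RH_Default_12	default
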