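subpopulation	n	n_uc	biomarkers	error	error_sd	auroc	auroc_sd
all	157	80	CRP,EGF,IL6,IL1a,MMP9NGAL,Osmolarity,CEA	0.203	0.017	0.766	0.152
cluster_blue	57	28	TNFa,EGF,NSE,NGAL,MMP9NGAL,TM,FAS	0.155	0.029	0.800	0.258
cluster_green	49	18	TNFa,EGF,IL6,IL1a,MMP9NGAL,TM,CEA	0.204	0.037	0.825	0.264
cluster_gold	23	15	CRP,sTNFR1,vWF,IL1a,MMP9NGAL,Creatinine,BTA	0.245	0.049	0.700	0.349
smokers	101	60	CRP,EGF,MMP9,IL1a,IL4,TM,IL2	0.276	0.027	0.770	0.117
non_smokers	56	20	TNFa,sTNFR1,IL6,IL1a,MMP9NGAL,Creatinine,CEA	0.156	0.027	0.783	0.159
males	120	65	CRP,EGF,CK18,IL1b,IL8,Creatinine,IL2	0.272	0.030	0.753	0.117
females	37	15	CRP,EGF,IL6,Ddimer,MMP9NGAL,Osmolarity,CEA	0.181	0.054	0.830	0.146
hx_stone_yes	30	14	CRP,sTNFR1,CK18,IL1a,IL8,Creatinine,VEGF	0.322	0.062	0.738	0.194
hx_stone_no	127	66	CRP,EGF,IL6,IL1a,MMP9NGAL,Creatinine,CEA	0.186	0.015	0.817	0.117
hx_bpe_yes	30	14	CRP,EGF,IL6,IL1a,MMP9NGAL,TM,CEA	0.192	0.018	0.826	0.148
hx_bpe_no	127	66	CRP,EGF,CK18,NGAL,MMP9NGAL,Creatinine,BTA	0.266	0.061	0.788	0.169
antihypertensive_yes	73	51	TNFa,EGF,IL6,Protein,MMP9NGAL,Creatinine,CEA	0.211	0.025	0.731	0.161
antihypertensive_no	83	28	TNFa,sTNFR1,IL6,NGAL,IL8,TM,CEA	0.145	0.028	0.810	0.132
antiplatelet_yes	37	25	TNFa,EGF,IL6,Protein,IL8,Osmolarity,CEA	0.215	0.019	0.780	0.141
antiplatelet_no	118	53	CRP,EGF,MCP1,Protein,MMP9NGAL,TM,FPSA	0.160	0.046	0.843	0.153
antiulcer_yes	33	17	CRP,EGF,IL6,IL1a,IL8,TM,CEA	0.220	0.018	0.827	0.118
antiulcer_no	123	62	CRP,EGF,vWF,IL1b,MMP9NGAL,TM,HA	0.259	0.072	0.812	0.168
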