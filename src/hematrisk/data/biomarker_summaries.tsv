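biomarker	block	unit	lod	cluster	median	q1	q3
CRP	black	ng/ml	0.67	blue	1.05	0.74	1.33
CRP	black	ng/ml	0.67	red	0.86	<0.67	0.91
CRP	black	ng/ml	0.67	green	1.06	0.84	1.25
CRP	black	ng/ml	0.67	purple	<0.67	<0.67	0.83
CRP	black	ng/ml	0.67	gold	0.75	<0.67	0.90
TNFa	black	pg/ml	0	blue	10.52	7.78	13.25
TNFa	black	pg/ml	0	red	9.07	7.36	9.79
TNFa	black	pg/ml	0	green	9.54	7.46	11.78
TNFa	black	pg/ml	0	purple	11.66	8.95	15.48
TNFa	black	pg/ml	0	gold	10.20	8.31	12.820
EGF	green	pg/ml	0	blue	7056	4965	13752
EGF	green	pg/ml	0	red	3633	1874	5992
EGF	green	pg/ml	0	green	6477	2784	10943
EGF	green	pg/ml	0	purple	3722.33	3058	4956
EGF	green	pg/ml	0	gold	13826	9488	20332
sTNFR1	green	pg/ml	0	blue	0.67	0.41	1.04
sTNFR1	green	pg/ml	0	red	0.75	0.47	1.05
sTNFR1	green	pg/ml	0	green	0.57	0.24	1.61
sTNFR1	green	pg/ml	0	purple	0.74	0.45	1.06
sTNFR1	green	pg/ml	0	gold	1.60	0.97	2.54
CK18	purple	ng/ml	0	blue	2.30	0.71	3.59
CK18	purple	ng/ml	0	red	1.22	0.42	2.78
CK18	purple	ng/ml	0	green	2.03	0.75	4.33
CK18	purple	ng/ml	0	purple	8.97	2.88	21.43
CK18	purple	ng/ml	0	gold	6.43	2.67	10.28
MCP1	purple	pg/ml	0	blue	112	38	212
MCP1	purple	pg/ml	0	red	73	41	141
MCP1	purple	pg/ml	0	green	67	28	113
MCP1	purple	pg/ml	0	purple	269	118	871
MCP1	purple	pg/ml	0	gold	237	106	550
NSE	purple	ng/ml	0.26	blue	BLOD	BLOD	BLOD
NSE	purple	ng/ml	0.26	red	0.28	<0.26	0.92
NSE	purple	ng/ml	0.26	green	BLOD	BLOD	BLOD
NSE	purple	ng/ml	0.26	purple	1.72	<0.26	18.32
NSE	purple	ng/ml	0.26	gold	0.51	<0.26	2.37
MMP9	purple	ng/ml	5.0	blue	BLOD	BLOD	BLOD
MMP9	purple	ng/ml	5.0	red	BLOD	BLOD	BLOD
MMP9	purple	ng/ml	5.0	green	BLOD	BLOD	BLOD
MMP9	purple	ng/ml	5.0	purple	15.15	6.57	50.81
MMP9	purple	ng/ml	5.0	gold	BLOD	BLOD	BLOD
IL6	purple	pg/ml	1.20	blue	1.37	<1.20	3.60
IL6	purple	pg/ml	1.20	red	12.93	3.27	26.67
IL6	purple	pg/ml	1.20	green	<1.20	<1.20	2.50
IL6	purple	pg/ml	1.20	purple	194.33	16.43	577.33
IL6	purple	pg/ml	1.20	gold	40.80	4.80	196.67
vWF	purple	IU/ml	0	blue	0.01	0.01	0.02
vWF	purple	IU/ml	0	red	0.01	0.00	0.01
vWF	purple	IU/ml	0	green	0.01	0.01	0.01
vWF	purple	IU/ml	0	purple	0.01	0.01	0.02
vWF	purple	IU/ml	0	gold	0.01	0.01	0.03
Protein	gold	mg/ml	0	blue	0.07	0.05	0.11
Protein	gold	mg/ml	0	red	0.44	0.29	0.60
Protein	gold	mg/ml	0	green	0.08	0.05	0.12
Protein	gold	mg/ml	0	purple	0.59	0.25	0.93
Protein	gold	mg/ml	0	gold	0.30	0.09	1.00
NGAL	gold	ng/ml	0	blue	123	92	212
NGAL	gold	ng/ml	0	red	192	146	297
NGAL	gold	ng/ml	0	green	110	74	148
NGAL	gold	ng/ml	0	purple	1379	602	1922
NGAL	gold	ng/ml	0	gold	464	108	1368
Ddimer	gold	ng/ml	2.10	blue	<2.10	<2.10	5.02
Ddimer	gold	ng/ml	2.10	red	47.01	11.80	138.27
Ddimer	gold	ng/ml	2.10	green	<2.10	<2.10	3.62
Ddimer	gold	ng/ml	2.10	purple	597.89	62.16	1493.69
Ddimer	gold	ng/ml	2.10	gold	58.35	<2.10	559.38
IL1a	gold	pg/ml	0	blue	0.90	0.90	2.52
IL1a	gold	pg/ml	0	red	2.42	1.01	3.53
IL1a	gold	pg/ml	0	green	0.90	0.90	1.01
IL1a	gold	pg/ml	0	purple	21.35	5.80	30.93
IL1a	gold	pg/ml	0	gold	2.47	0.90	81.00
IL1b	gold	pg/ml	1.60	blue	BLOD	BLOD	BLOD
IL1b	gold	pg/ml	1.60	red	BLOD	BLOD	BLOD
IL1b	gold	pg/ml	1.60	green	BLOD	BLOD	BLOD
IL1b	gold	pg/ml	1.60	purple	17.80	5.46	78.87
IL1b	gold	pg/ml	1.60	gold	<1.60	<1.60	19.12
IL8	pink	pg/ml	0	blue	32.40	7.93	265.83
IL8	pink	pg/ml	0	red	292.67	117.33	604.33
IL8	pink	pg/ml	0	green	28.63	7.90	135.33
IL8	pink	pg/ml	0	purple	2900	2064	2900
IL8	pink	pg/ml	0	gold	875.67	48.40	2900
MMP9NGAL	pink	ratio	0	blue	0.09	0.08	0.10
MMP9NGAL	pink	ratio	0	red	0.16	0.10	0.29
MMP9NGAL	pink	ratio	0	green	0.07	0.07	0.09
MMP9NGAL	pink	ratio	0	purple	0.29	0.23	0.48
MMP9NGAL	pink	ratio	0	gold	0.23	0.09	0.29
IL4	pink	pg/ml	6.60	blue	BLOD	BLOD	BLOD
IL4	pink	pg/ml	6.60	red	BLOD	BLOD	BLOD
IL4	pink	pg/ml	6.60	green	BLOD	BLOD	BLOD
IL4	pink	pg/ml	6.60	purple	<6.60	<6.60	6.80
IL4	pink	pg/ml	6.60	gold	BLOD	BLOD	BLOD
sTNFR2	pink	pg/ml	0.15	blue	BLOD	BLOD	BLOD
sTNFR2	pink	pg/ml	0.15	red	<0.15	<0.15	0.26
sTNFR2	pink	pg/ml	0.15	green	<0.15	<0.15	0.26
sTNFR2	pink	pg/ml	0.15	purple	BLOD	BLOD	BLOD
sTNFR2	pink	pg/ml	0.15	gold	<0.15	<0.15	0.61
Creatinine	blue	umol/L	0	blue	9608	7961	13360
Creatinine	blue	umol/L	0	red	5605	4454	11945
Creatinine	blue	umol/L	0	green	7115	3868	12595
Creatinine	blue	umol/L	0	purple	7600	5360	8625
Creatinine	blue	umol/L	0	gold	14087	12405	17245
Osmolarity	blue	mOsm	0	blue	536	450	741
Osmolarity	blue	mOsm	0	red	462	276	560
Osmolarity	blue	mOsm	0	green	526	278	675
Osmolarity	blue	mOsm	0	purple	404	314	482
Osmolarity	blue	mOsm	0	gold	644	567	7840
TM	blue	ng/ml	0	blue	4.08	3.19	4.97
TM	blue	ng/ml	0	red	3.97	1.55	5.69
TM	blue	ng/ml	0	green	4.00	1.74	5.68
TM	blue	ng/ml	0	purple	3.49	2.65	4.00
TM	blue	ng/ml	0	gold	6.30	5.34	8.86
IL2	yellow	pg/ml	0	blue	5.61	5.21	5.92
IL2	yellow	pg/ml	0	red	5.24	5.02	5.65
IL2	yellow	pg/ml	0	green	5.45	5.20	6.27
IL2	yellow	pg/ml	0	purple	6.89	5.99	7.24
IL2	yellow	pg/ml	0	gold	5.99	5.65	7.20
CEA	yellow	ng/ml	0	blue	1.57	1.16	2.58
CEA	yellow	ng/ml	0	red	1.59	1.15	3.23
CEA	yellow	ng/ml	0	green	1.36	0.87	2.10
CEA	yellow	ng/ml	0	purple	1.77	1.30	2.39
CEA	yellow	ng/ml	0	gold	1.37	0.89	2.80
HA	yellow	ng/ml	0	blue	685	439	866
HA	yellow	ng/ml	0	red	835	595	1005
HA	yellow	ng/ml	0	green	594	282	900
HA	yellow	ng/ml	0	purple	1569	1143	1846
HA	yellow	ng/ml	0	gold	1258	883	1712
FPSA	yellow	ng/ml	0	blue	0.09	0.04	0.21
FPSA	yellow	ng/ml	0	red	0.05	0.04	0.23
FPSA	yellow	ng/ml	0	green	0.07	0.04	0.12
FPSA	yellow	ng/ml	0	purple	0.13	0.07	0.30
FPSA	yellow	ng/ml	0	gold	0.05	0.04	0.10
BTA	yellow	U/ml	0	blue	8.52	2.57	38.96
BTA	yellow	U/ml	0	red	248.01	206.82	394.15
BTA	yellow	U/ml	0	green	6.27	1.21	17.92
BTA	yellow	U/ml	0	purple	278.41	226.40	504.33
BTA	yellow	U/ml	0	gold	213.00	15.24	476.28
VEGF	yellow	ng/ml	0	blue	88	37	271
VEGF	yellow	ng/ml	0	red	96	76	220
VEGF	yellow	ng/ml	0	green	78	38	122
VEGF	yellow	ng/ml	0	purple	1266	414	1500
VEGF	yellow	ng/ml	0	gold	253	79	621
FAS	yellow	pg/ml	0	blue	64	42	96
FAS	yellow	pg/ml	0	red	83	60	128
FAS	yellow	pg/ml	0	green	56	37	86
FAS	yellow	pg/ml	0	purple	214	106	475
FAS	yellow	pg/ml	0	gold	200	96	279
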