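cluster	pTa	pT1	pT2a	pT2b	pT3a	pT3b	pT4a	CIS
blue	18	7	1	0	0	0	1	1
red	3	1	3	0	0	0	0	1
green	16	1	1	0	0	0	0	0
purple	5	2	2	2	0	0	0	0
gold	5	2	3	0	1	3	1	0
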