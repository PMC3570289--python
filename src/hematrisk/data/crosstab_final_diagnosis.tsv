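cluster	no_diagnosis	benign	stones_inflammation	BPE	other_cancers	NMI_UC	MI_UC
blue	16	1	6	6	0	26	2
red	3	0	1	1	0	5	3
green	14	5	6	4	2	17	1
purple	0	0	0	1	3	7	4
gold	3	0	4	0	1	7	8
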