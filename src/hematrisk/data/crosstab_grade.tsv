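cluster	grade1	grade2	grade3
blue	2	15	10
red	0	2	5
green	0	14	4
purple	1	3	7
gold	1	5	9
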