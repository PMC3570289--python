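cluster	grade1	grade2	grade3
blue	2	13	3
red	0	2	1
green	0	14	2
purple	1	3	1
gold	1	3	1
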