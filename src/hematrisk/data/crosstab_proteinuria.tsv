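cluster	normal	proteinuria
blue	54	3
red	2	11
green	43	6
purple	3	12
gold	10	13
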