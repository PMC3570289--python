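cluster	benign	malignant
blue	38	11
red	7	6
green	41	2
purple	8	6
gold	9	11
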