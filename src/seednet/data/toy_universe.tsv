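source	target	is_directed	is_stimulation	is_inhibition	form_complex
A	B	1	1	0	0
B	C	1	0	1	0
A	D	1	1	0	0
D	C	1	1	0	0
E	A	1	1	0	0
C	E	1	0	1	0
F	C	1	0	0	0
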