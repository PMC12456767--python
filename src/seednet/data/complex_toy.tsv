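source	target	is_directed	is_stimulation	is_inhibition	form_complex
P	CPLX1	0	0	0	1
Q	CPLX1	0	0	0	1
P	A	1	1	0	0
CPLX1	B	1	0	1	0
A	CPLX1	1	1	0	0
A	B	1	1	0	0
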