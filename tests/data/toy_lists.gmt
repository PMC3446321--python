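A	.	g0010	g0012	g0016	g0027	g0035	g0049	g0053	g0054
B	.	g0000	g0004	g0006	g0021	g0045	g0057
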