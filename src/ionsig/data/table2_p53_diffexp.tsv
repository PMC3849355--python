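symbol	fold_change	p_adj
ANO1	0.66	0.001
CACNA1D	0.32	<0.001
CACNA2D1	0.79	0.002
CACNA2D2	0.47	<0.001
CLCA2	2.53	0.039
CLIC5	0.77	<0.001
CLIC6	0.28	<0.001
GLRB	0.32	<0.001
KCND3	0.46	<0.001
KCNE3	1.34	<0.001
KCNE4	0.25	<0.001
KCNJ3	0.51	<0.001
KCNK1	1.44	<0.001
KCNK6	0.80	0.010
KCNMA1	0.65	<0.001
KCNN4	1.69	<0.001
MCOLN2	1.60	<0.001
P2RX4	0.73	<0.001
SCN7A	0.29	<0.001
SCNN1A	0.71	<0.001
TPCN1	0.77	<0.001
TRPC1	0.72	0.005
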