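symbol	rho	p_adj
ANO1	-0.23	<0.001
CACNA1D	-0.42	<0.001
CACNA2D1	-0.28	<0.001
CACNA2D2	-0.30	<0.001
CLIC1	0.26	<0.001
CLIC4	0.16	0.022
CLIC5	-0.22	0.001
CLIC6	-0.33	<0.001
GLRB	-0.35	<0.001
KCNAB2	0.15	0.023
KCND3	-0.39	<0.001
KCNE3	0.23	<0.001
KCNE4	-0.38	<0.001
KCNK1	0.25	<0.001
KCNMA1	-0.30	<0.001
KCNN4	0.23	<0.001
MCOLN2	0.25	<0.001
P2RX4	-0.24	<0.001
PKD1	-0.17	0.012
PKD2	-0.19	0.004
SCN1B	-0.27	<0.001
SCN7A	-0.41	<0.001
SCNN1A	-0.18	0.008
TPCN1	-0.26	<0.001
TPCN2	0.17	0.013
TRPC1	-0.25	<0.001
TRPM4	-0.21	0.002
VDAC1	0.21	0.002
VDAC2	0.22	0.001
VDAC3	0.26	<0.001
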