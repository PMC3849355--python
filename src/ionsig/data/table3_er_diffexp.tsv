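symbol	fold_change	p_adj
ANO1	2.09	<0.001
CACNA1A	0.65	0.043
CACNA1D	5.59	<0.001
CACNA2D1	1.30	0.033
CACNA2D2	2.61	<0.001
CLCA2	0.46	0.017
CLIC4	0.75	0.008
CLIC6	5.86	<0.001
GABRP	0.20	0.020
GLRB	3.42	<0.001
KCNAB2	0.72	0.013
KCND3	2.36	<0.001
KCNE3	0.75	0.003
KCNE4	12.64	<0.001
KCNJ3	6.22	<0.001
KCNK6	1.82	<0.001
KCNMA1	1.45	0.035
KCNN4	0.42	<0.001
KCNS3	1.58	0.028
MCOLN2	0.46	0.002
P2RX4	1.82	<0.001
SCN7A	1.71	0.009
SCNN1A	2.00	<0.001
TPCN1	1.38	<0.001
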