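symbol	weight
ANO1	-0.23
CACNA1D	-0.42
CACNA2D1	-0.28
CACNA2D2	-0.30
CLIC1	0.26
CLIC4	0.16
CLIC5	-0.22
CLIC6	-0.33
GLRB	-0.35
KCNAB2	0.15
KCND3	-0.39
KCNE3	0.23
KCNE4	-0.38
KCNK1	0.25
KCNMA1	-0.30
KCNN4	0.23
MCOLN2	0.25
P2RX4	-0.24
PKD1	-0.17
PKD2	-0.19
SCN1B	-0.27
SCN7A	-0.41
SCNN1A	-0.18
TPCN1	-0.26
TPCN2	0.17
TRPC1	-0.25
TRPM4	-0.21
VDAC1	0.21
VDAC2	0.22
VDAC3	0.26
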