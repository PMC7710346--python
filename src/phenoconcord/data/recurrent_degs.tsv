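gene	n_phenotypes	log2fc	direction
CDKN1C	11	1.10845	up
MECP2	11	0.37637	up
NFIX	10	0.413196	up
LIMK1	9	0.563392	up
FLNA	9	0.535682	up
BCL7B	9	0.419455	up
WBSCR16	9	0.30959	up
FLII	9	0.23419	up
COG6	9	-0.334932	down
NRAS	9	-0.34015	down
TCF4	9	-0.351494	down
ATRX	9	-0.377614	down
KRAS	9	-0.427387	down
PTEN	9	-0.524188	down
DHFR	9	-0.565876	down
WBSCR27	9	-3.16821	down
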