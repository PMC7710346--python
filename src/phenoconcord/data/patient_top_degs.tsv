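gene	log2fc	p_value	q_value
USP32P2	-6.312	5.00E-05	0.000316967
ADAMTS2	-4.49852	0.00025	0.00129193
HIST1H1E	-4.31541	5.00E-05	0.000316967
THBS1	-4.04863	5.00E-05	0.000316967
SULT1A2	-3.87789	0.00655	0.019417
HIST1H1D	-3.83365	0.00015	0.000841735
RMRP	-3.57236	5.00E-05	0.000316967
RPPH1	-3.5139	5.00E-05	0.000316967
RAVER2	-3.42626	0.0004	0.00193051
ANKRD34B	-3.41265	0.00035	0.00172049
WBSCR27	-3.16821	0.0077	0.0223024
SCARNA2	-3.09253	5.00E-05	0.000316967
PRR29	3.06369	0.00145	0.00555477
TFCP2L1	3.26474	5.00E-05	0.000316967
VMO1	3.3094	5.00E-05	0.000316967
VSIG2	3.55333	0.0196	0.0477048
HERC2P3	3.63294	5.00E-05	0.000316967
SH3RF2	3.70726	0.00385	0.0124584
GRIK4	3.95099	0.0002	0.00107189
TM4SF19	4.23945	0.00115	0.00461064
TACSTD2	4.99907	0.0026	0.00902676
CYP4F29P	5.07494	0.0001	0.000592077
USP32P1	5.78815	5.00E-05	0.000316967
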