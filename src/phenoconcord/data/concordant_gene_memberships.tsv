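gene	patient_blood	wang_organoid	wang_neurons	wang_npc	wilkinson_npc	sugathan_npc	phenotypes
TCF4	1	1	1	1	1	0	facial_dysmorphisms;dd;id;asd;speech_delay;gi;dental;pes_planus;hypotonia
NFIA	1	1	1	1	1	0	anxiety;gi;hypotonia
RGMB	1	1	1	1	1	0	asd
CELF2	1	1	1	1	1	0
EML6	1	1	1	1	1	1
FBXL19	1	1	1	1	1	1
PODXL	1	1	1	1	1	0
RIMS3	1	0	1	1	1	1
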