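phenotype	n_overlap	psg_size
facial_dysmorphisms	212	832
dd	240	833
id	327	1236
asd	113	482
speech_delay	124	494
macrocephaly	103	378
pes_planus	62	181
hypotonia	258	937
gi	206	740
sleep	90	352
anxiety	101	372
dental	235	824
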