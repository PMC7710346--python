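model	n_degs
patient_blood	5388
wang_neurons	3289
wilkinson_npc	1812
wang_npc	1248
wang_organoid	838
sugathan_npc	369
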