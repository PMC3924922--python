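von Willebrand factor and factor VIII levels	VWF_LOCUS
Hippocampal atrophy	HA_LOCUS
Atrial fibrillation	AF_LOCUS
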