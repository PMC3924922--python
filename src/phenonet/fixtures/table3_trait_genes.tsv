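Iron status biomarkers	IB_LOCUS
Cognitive performance	CP_LOCUS
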