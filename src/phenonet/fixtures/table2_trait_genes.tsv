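HDL cholesterol	APOE
HDL cholesterol	APOC1
HDL cholesterol	PVRL2
HDL cholesterol	TOMM4
Alzheimer's disease	APOE
Alzheimer's disease	APOC1
Alzheimer's disease	PVRL2
Alzheimer's disease	TOMM4
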