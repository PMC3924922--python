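VWF_LOCUS	[5412] Arrhythmogenic right ventricular cardiomyopathy
VWF_LOCUS	[4662] B cell receptor signaling pathway
VWF_LOCUS	[4514] Cell adhesion molecules (CAMs)
VWF_LOCUS	[4062] Chemokine signaling pathway
VWF_LOCUS	[4664] Fc epsilon RI signaling pathway
VWF_LOCUS	[1100] Metabolic pathways
VWF_LOCUS	[4666] Fc gamma R-mediated phagocytosis
VWF_LOCUS	[4510] Focal adhesion
VWF_LOCUS	[4670] Leukocyte trans endothelial migration
VWF_LOCUS	[4650] Natural killer cell mediated cytotoxicity
VWF_LOCUS	[4810] Regulation of actin cytoskeleton
VWF_LOCUS	[4660] T cell receptor signaling pathway
VWF_LOCUS	[4742] Taste transduction
AF_LOCUS	[1100] Metabolic pathways
AF_LOCUS	[670] One carbon pool by folate
HA_LOCUS	[4360] Axon guidance
HA_LOCUS	[4623] Cytosolic DNA-sensing pathway
HA_LOCUS	[531] Glycosaminoglycan degradation
HA_LOCUS	[4142] Lysosome
HA_LOCUS	[1100] Metabolic pathways
HA_LOCUS	[510] N-Glycan biosynthesis
HA_LOCUS	[4151] PI3K-Akt signaling pathway
HA_LOCUS	[4141] Protein processing in endoplasmic reticulum
HA_LOCUS	[4530] Tight junction
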