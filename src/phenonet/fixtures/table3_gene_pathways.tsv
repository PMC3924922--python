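IB_LOCUS	[4142] Lysosome
IB_LOCUS	[1100] Metabolic pathways
IB_LOCUS	[4978] Mineral absorption
IB_LOCUS	[3060] Protein export
IB_LOCUS	[4060] Cytokine-cytokine receptor interaction
IB_LOCUS	[531] Glycosaminoglycan degradation
IB_LOCUS	[4066] HIF-1 signaling
IB_LOCUS	[4080] Neuroactive ligand-receptor interaction
IB_LOCUS	[4151] PI3K-Akt signaling
IB_LOCUS	[4630] Jak-STAT signaling
IB_LOCUS	[4120] Ubiquitin mediated proteolysis
CP_LOCUS	[5143] African trypanosomiasis
CP_LOCUS	[5034] Alcoholism
CP_LOCUS	[5010] Alzheimers disease
CP_LOCUS	[5146] Amoebiasis
CP_LOCUS	[5142] Chagas disease (American trypanosomiasis)
CP_LOCUS	[4961] Endocrine and other factor-regulated calcium reabsorption
CP_LOCUS	[650] Butanoate metabolism
CP_LOCUS	[4020] Calcium signaling
CP_LOCUS	[5031] Amphetamine addiction
CP_LOCUS	[4062] Chemokine signaling
CP_LOCUS	[280] Valine leucine and isoleucine degradation
CP_LOCUS	[4713] Circadian entrainment
CP_LOCUS	[5030] Cocaine addiction
CP_LOCUS	[4728] Dopaminergic synapse
CP_LOCUS	[5014] Amyotrophic lateral sclerosis (ALS)
CP_LOCUS	[4144] Endocytosis
CP_LOCUS	[5169] Epstein-Barr virus infection
CP_LOCUS	[71] Fatty acid metabolism
CP_LOCUS	[4510] Focal adhesion
CP_LOCUS	[4727] GABAergic synapse
CP_LOCUS	[4540] Gap junction
CP_LOCUS	[4971] Gastric acid secretion
CP_LOCUS	[4724] Glutamatergic synapse
CP_LOCUS	[4912] GnRH signaling
CP_LOCUS	[4066] HIF-1 signaling
CP_LOCUS	[5016] Huntingtons disease
CP_LOCUS	[562] Inositol phosphate metabolism
CP_LOCUS	[4730] Long-term depression
CP_LOCUS	[4720] Long-term potentiation
CP_LOCUS	[310] Lysine degradation
CP_LOCUS	[4916] Melanogenesis
CP_LOCUS	[1100] Metabolic pathways
CP_LOCUS	[5032] Morphine addiction
CP_LOCUS	[4080] Neuroactive ligand-receptor interaction
CP_LOCUS	[5033] Nicotine addiction
CP_LOCUS	[4330] Notch signaling
CP_LOCUS	[670] One carbon pool by folate
CP_LOCUS	[4151] PI3K-Akt signaling
CP_LOCUS	[3320] PPAR signaling
CP_LOCUS	[4972] Pancreatic secretion
CP_LOCUS	[4146] Peroxisome
CP_LOCUS	[4070] Phosphatidylinositol signaling system
CP_LOCUS	[640] Propanoate metabolism
CP_LOCUS	[3060] Protein export
CP_LOCUS	[4723] Retrograde endocannabinoid signaling
CP_LOCUS	[5323] Rheumatoid arthritis
CP_LOCUS	[4970] Salivary secretion
CP_LOCUS	[4726] Serotonergic synapse
CP_LOCUS	[4721] Synaptic vesicle cycle
CP_LOCUS	[5322] Systemic lupus erythematosus
CP_LOCUS	[5202] Transcriptional misregulation in cancer
CP_LOCUS	[380] Tryptophan metabolism
CP_LOCUS	[4725] Cholinergic synapse
CP_LOCUS	[4270] Vascular smooth muscle contraction
CP_LOCUS	[4310] Wnt signaling
CP_LOCUS	[410] beta-Alanine metabolism
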