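APOE	[2010] ABC transporters
APOE	[4520] Adheren's junction
APOE	[5014] Amyotrophic lateral sclerosis (ALS)
APOE	[4514] Cell adhesion molecules (CAMs)
APOE	[4610] Complement and coagulation cascades
APOE	[5168] Herpes simplex infection
APOC1	[2010] ABC transporters
APOC1	[4520] Adheren's junction
APOC1	[5014] Amyotrophic lateral sclerosis (ALS)
APOC1	[4514] Cell adhesion molecules (CAMs)
APOC1	[4610] Complement and coagulation cascades
APOC1	[5168] Herpes simplex infection
PVRL2	[2010] ABC transporters
PVRL2	[4520] Adheren's junction
PVRL2	[5014] Amyotrophic lateral sclerosis (ALS)
PVRL2	[4514] Cell adhesion molecules (CAMs)
PVRL2	[4610] Complement and coagulation cascades
PVRL2	[5168] Herpes simplex infection
TOMM4	[2010] ABC transporters
TOMM4	[4520] Adheren's junction
TOMM4	[5014] Amyotrophic lateral sclerosis (ALS)
TOMM4	[4514] Cell adhesion molecules (CAMs)
TOMM4	[4610] Complement and coagulation cascades
TOMM4	[5168] Herpes simplex infection
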