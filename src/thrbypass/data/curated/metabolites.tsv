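id	name	carbons	is_cofactor	is_boundary
Glc	D-glucose	6	0	1
PGA	3-phosphoglycerate	3	0	0
PEP	phosphoenolpyruvate	3	0	0
Pyr	pyruvate	3	0	0
OAA	oxaloacetate	4	0	0
Asp	L-aspartate	4	0	0
Thr	L-threonine	4	0	0
AKB	2-amino-3-ketobutyrate	4	0	0
Gly	glycine	2	0	0
Ser	L-serine	3	0	0
Glu	L-glutamate	5	0	0
AKG	2-oxoglutarate	5	0	0
AcCoA	acetyl-CoA (acetyl moiety)	2	1	0
CoA	coenzyme A	0	1	0
THF	tetrahydrofolate	0	1	0
MTHF	methylene-THF (methylene moiety)	1	1	0
ATP	ATP	0	1	0
ADP	ADP	0	1	0
AMP	AMP	0	1	0
NAD	NAD+	0	1	0
NADH	NADH	0	1	0
NADP	NADP+	0	1	0
NADPH	NADPH	0	1	0
CO2	carbon dioxide	1	0	1
NH4	ammonium	0	0	1
Pi	inorganic phosphate	0	0	1
O2	molecular oxygen	0	0	1
H2O	water	0	0	1
PHB	3-hydroxybutyrate monomer	4	0	1
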