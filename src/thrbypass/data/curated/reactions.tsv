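id	equation	lower_bound	upper_bound	name
EX_glc	Glc -> 	-10.0	1000.0	glucose exchange
EX_o2	O2 -> 	-1000.0	1000.0	oxygen exchange
EX_co2	CO2 -> 	-1000.0	1000.0	CO2 exchange
EX_nh4	NH4 -> 	-1000.0	1000.0	ammonium exchange
EX_pi	Pi -> 	-1000.0	1000.0	phosphate exchange
EX_h2o	H2O -> 	-1000.0	1000.0	water exchange
EX_phb	PHB -> 	0.0	1000.0	PHB monomer sink
emp	Glc + 2 NAD -> 2 PGA + 2 NADH	0.0	1000.0	EMP glycolysis to 3-phosphoglycerate (PTS convention)
eno	PGA -> PEP + H2O	0.0	1000.0	phosphoglycerate mutase + enolase
pyk	PEP + ADP -> Pyr + ATP	0.0	1000.0	pyruvate kinase
pdh	Pyr + CoA + NAD -> AcCoA + CO2 + NADH	0.0	1000.0	pyruvate dehydrogenase complex
ppc	PEP + CO2 -> OAA + Pi	0.0	1000.0	PEP carboxylase
pps	Pyr + ATP + H2O -> PEP + AMP + Pi	0.0	1000.0	PEP synthase (ATP -> AMP, 2 ATP-equivalents)
adk	ATP + AMP -> 2 ADP	-1000.0	1000.0	adenylate kinase
aspC	OAA + Glu -> Asp + AKG	-1000.0	1000.0	aspartate transaminase
gdh	AKG + NH4 + NADPH -> Glu + NADP + H2O	0.0	1000.0	glutamate dehydrogenase (NADPH)
thr_synth	Asp + 2 ATP + 2 NADPH -> Thr + 2 ADP + 2 NADP + 2 Pi	0.0	1000.0	threonine synthesis from aspartate (5 steps, lumped)
tdh	Thr + NAD -> AKB + NADH	0.0	1000.0	threonine dehydrogenase
kbl	AKB + CoA -> AcCoA + Gly	0.0	1000.0	2-amino-3-ketobutyrate CoA ligase
glyA	Gly + MTHF + H2O -> Ser + THF	0.0	1000.0	serine hydroxymethyltransferase (glycine -> serine)
gcv	Gly + THF + NAD -> MTHF + CO2 + NH4 + NADH	0.0	1000.0	glycine cleavage system
sdaA	Ser -> Pyr + NH4	0.0	1000.0	serine deaminase
serB	PGA + NAD + Glu -> Ser + NADH + AKG + Pi	0.0	1000.0	serine de novo synthesis from PGA (serA/serC/serB, lumped)
phaCAB	2 AcCoA + NADPH -> PHB + 2 CoA + NADP	0.0	1000.0	PHB monomer synthesis (phaA/phaB/phaC, lumped)
resp	NADH + 1/2 O2 + 56/33 ADP + 56/33 Pi -> NAD + 56/33 ATP + H2O	0.0	1000.0	lumped respiration (atp_per_nadh ATP per NADH)
atpm	ATP + H2O -> ADP + Pi	0.0	1000.0	ATP hydrolysis drain
pntAB	NADH + NADP -> NAD + NADPH	-1000.0	1000.0	transhydrogenase
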