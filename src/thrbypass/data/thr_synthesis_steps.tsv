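reaction_id	equation
thrA_kinase	Asp + ATP -> A4P + ADP
asd	A4P + NADPH -> ASA + NADP + Pi
thrA_hdh	ASA + NADPH -> Hser + NADP
thrB	Hser + ATP -> PHS + ADP
thrC	PHS -> Thr + Pi
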