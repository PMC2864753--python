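day	locus_id	gene	description	ratio	p_value
18	SAR11_1238	sfuC	Iron(III) ABC transporter: periplasmic	11.41	0.000
18	SAR11_1274	cspL	DNA-binding cold shock protein	6.20	0.000
18	SAR11_0161	groES	Protein-folding chaperonin	2.01	0.028
18	SAR11_1062	dapA	Dihydrodipicolinate synthase	1.53	0.849
28	SAR11_1238	sfuC	Iron(III) ABC transporter: periplasmic	26.96	0.000
28	SAR11_1161	sbcC	ATPase involved in DNA repair	4.59	0.011
28	SAR11_0161	groES	Protein-folding chaperonin	3.59	0.008
28	SAR11_0601	ftsH	Metalloprotease	3.28	0.001
28	SAR11_1124	rplL	50S ribosomal protein L31	3.16	0.006
28	SAR11_0430	aceF	Dihydrolipoamide S-acetyltransferase	3.02	0.094
28	SAR11_0171		Rhodanese-related sulfurtransferase	2.74	0.002
28	SAR11_0791		Ring-cleaving dioxygenase	2.42	0.336
28	SAR11_1274	cspL	DNA-binding cold shock protein	2.27	0.437
28	SAR11_0235	pdhD	Dihydrolipoyl dehydrogenase	2.26	0.035
28	SAR11_0401		Conserved hypothetical protein	2.21	0.003
28	SAR11_0054	pilA	Pilin protein	2.16	0.020
28	SAR11_0727	accB	Acetyl-CoA carboxylase	2.03	0.301
28	SAR11_0987	ppiB	Peptidylprolyl isomerase	1.99	0.291
28	SAR11_0793		Unknown protein	1.74	0.128
28	SAR11_0599		Hypothetical protein	1.70	0.623
28	SAR11_0708	acpP	Acyl carrier protein	1.55	0.198
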