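locus_id	gene	description	ratio	p_value	cluster
SAR11_0144		Conserved hypothetical protein	1.54	0.001	early
SAR11_0333	hslV	ATP-dependent protease: peptidase	1.63	0.000	stationary
SAR11_0334	hslU	ATP-dependent protease: ATP-binding	1.59	0.035	
SAR11_0399	rbr	Rubrerythrin, hyp. ferroxidase (Fe2+ to Fe3+)	1.57	0.025	
SAR11_0738	sufA	Transcriptional regulator	1.76	0.062	stationary
SAR11_0739	sufB	Cysteine desulfurase activator complex	2.00	0.009	early
SAR11_0740	sufC	FeS assembly ATPase	1.80	0.017	early
SAR11_0741	sufD	FeS assembly protein	2.29	0.019	early
SAR11_0742	csdB	Selenocysteine lyase chain A	2.44	0.046	early
SAR11_0743	sufE	Putative NifU-like protein	2.24	0.004	late
SAR11_0744	paaD	Phenylacetic acid degradation protein	2.00	0.001	early
SAR11_0745	hesB	HesB protein	1.95	0.000	early
SAR11_0785		Conserved hypothetical protein (DUF952)	1.52	0.051	late
SAR11_1233		Domain of unknown function (DUF931)	3.36	0.001	early
SAR11_1235	azlC	AzlC protein	2.14	0.016	early
SAR11_1236	sfuA	Iron(III) ABC transporter: ATP-binding	4.99	0.000	early
SAR11_1237	sfuB	Iron(III) ABC transporter: permease	10.36	0.000	early
SAR11_1238	sfuC	Iron(III) ABC transporter: periplasmic	16.00	0.003	early
SAR11_1239		Unknown protein	2.47	0.006	late
SAR11_1240	aceA	Isocitrate lyase	1.58	0.091	late
SAR11_1242		Transcription regulator	1.60	0.054	late
SAR11_1253	dmgdh	Dimethylglycine dehydrogenase	1.54	0.054	late
SAR11_1279		Unknown membrane protein	1.56	0.056	
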