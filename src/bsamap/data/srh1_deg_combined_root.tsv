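gene_id	chrom	pos	log2fc	fdr	annotation
TraesCS5B02G406100	5B		-5.5982	2.62E-07	bHLH protein
TraesCS1D02G347400	1D		-5.1297	2.67E-03	Protein kinase (putative)
TraesCS4D02G313800	4D		-4.4859	6.08E-05	Phosphate transporter protein
TraesCS2A02G207200	2A		-3.3756	9.92E-03	GDSL esterase/lipase
TraesCS7B02G010700	7B		-3.1662	2.78E-02	GDSL esterase/lipase
TraesCS2B02G174300	2B		-3.044	3.95E-04	Peroxidase
TraesCS5A02G401300	5A		-3.0248	2.47E-07	bHLH protein
TraesCS6A02G030900	6A		-2.7436	6.74E-04	High affinity nitrate transporter
TraesCS6A02G031100	6A		-2.6138	3.97E-04	High affinity nitrate transporter
TraesCS7B02G264400	7B		-2.537	7.49E-03	Cytokinin oxidase/dehydrogenase
TraesCS4B02G317200	4B		-2.4487	5.43E-05	Phosphate transporter protein
TraesCS6B02G044100	6B		-2.4042	7.64E-08	High affinity nitrate transporter
TraesCS6D02G035700	6D		-2.2051	2.65E-03	High affinity nitrate transporter
TraesCS3D02G514400	3D		-2.0713	1.49E-03	NAD-dependent epimerase/dehydratase
TraesCS3A02G399000	3A	646100000	-2.0414	5.18E-52	Calreticulin-3 chaperone
TraesCS2B02G368400	2B		-2.0044	3.61E-03	Nitrate transporter
TraesCS3D02G416800	3D		-1.882	2.59E-10	Loricrin
TraesCS3A02G187200	3A		-1.8562	8.44E-23	NEDD8-activating enzyme E1 catalytic subunit
TraesCS3A02G248000	3A		-1.7809	2.59E-10	Alpha-amylase
TraesCS4B02G033400	4B		-1.7632	2.75E-03	Germin-like protein 1
TraesCS3A02G434400	3A	676200000	-1.7003	1.27E-13	MADS box transcription factor
TraesCS5B02G152400	5B		-1.6506	3.62E-03	Calcium binding protein
TraesCS3A02G295900	3A	530200000	-1.65	1.05E-17	Ubiquitin carboxyl-terminal hydrolase (putative)
TraesCS3D02G223600	3D		-1.5127	1.28E-03	Octicosapeptide/Phox/Bem1p domain containing protein
TraesCS7A02G101300	7A		1.5331	3.40E-04	Cytochrome P450 family protein
TraesCS4D02G197500	4D		1.66889	1.22E-06	Phosphatidylinositol transfer protein
TraesCS2D02G442900	2D		1.73303	1.74E-03	Peptide transporter
TraesCS3B02G539500	3B		1.88995	4.12E-06	Cytochrome P450 family protein
TraesCS3B02G424600	3B		2.93918	3.62E-03	DELLA protein
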