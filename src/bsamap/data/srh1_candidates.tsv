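gene_id	chrom	pos	cds_pos	ref	alt	aa_change	consequence	annotation	sift	conservation_pct
TraesCS3A02G347600	3A	596743515	1166	G	A	G389E	missense	Glutamyl-tRNA amidotransferase subunit A	0	95
TraesCS3A02G351500	3A	600007728	1799	A	G	D600	missense	Protein kinase	0	95
TraesCS3A02G354200	3A	601558511	1427	C	T	A476V	missense	Respiratory burst oxidase-like protein	0	90
TraesCS3A02G361700	3A	609947615	187	G	A	E63K	missense	Pumilio-like protein	0	84
TraesCS3A02G363900	3A	612526030	1103	C	T	P368L	missense	BEL1-like homeodomain protein	0	94
TraesCS3A02G364400	3A	613172884	1459	A	G	S487G	missense	Rop guanine nucleotide exchange factor	0.04	96
TraesCS3A02G367700	3A	616705229	693	G	T	E231D	missense	Pentatricopeptide repeat-containing protein	0	86
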