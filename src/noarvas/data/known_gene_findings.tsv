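patient	gene	accession	hgvs_c	hgvs_p	location	validation	inheritance_model	effect	zygosity	chromosome
P19	TEX15	NM_031271.3	c.3098ATGCAATAAT[2>1]	p.Cys1037Serfs*47	Exon 1	True	AR	frameshift	heterozygous	chr8
P58	BRCA2	NM_000059.3	c.5864C>G	p.Ser1955*	Exon 11	True	AD	nonsense	heterozygous	chr13
P58	FAM47C	NM_001013736.3	c.351_352insCTTC	p.Val118Leufs*40	Exon 1	True	XL	frameshift	hemizygous	chrX
P80	MEIOB	NM_001163560.2	c.1A>G	p.0?	Exon 2	True	AR	start_codon_loss	heterozygous	chr16
P82	BRCA2	NM_000059.3	c.6590_6592delCTG	p.Thr2197_Glu2198delinsLys	Exon 11	True	AD	indel_inframe	heterozygous	chr13
P88	SYCP3	NM_153694.4	c.-13-2A>C	NA	Intron 1	True	AD	splice_acceptor	heterozygous	chr12
P101	TDRD7	NM_014290.2	c.3121C>T	p.Arg1041*	Exon 17	True	AR	nonsense	heterozygous	chr9
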