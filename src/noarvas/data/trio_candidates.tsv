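proband	gene	hgvs_c	hgvs_p	accession	inheritance	effect	zygosity	chromosome	validation	ne	p_rvas	or_rvas	network
P6	PRPF40B	c.349-2A>C	NA	NM_001031698.2	de_novo	splice_acceptor	heterozygous	chr12	False	25.1	0.0018	not_estimable	Linked
P38	LAMA4	c.5336delG	p.Ser1779Thrfs*12	NM_002290.4	maternal	frameshift	heterozygous	chr6	True	9.4	0.2880	3.7321	NA
P38	NDUFAF1	c.383G[5>4]	p.Glu131Lysfs*8	NM_016013.3	maternal	frameshift	heterozygous	chr15	True	14.1	0.0268	not_estimable	NA
P38	UMODL1	c.3474+1G>C	NA	NM_001199528.2	maternal	splice_donor	heterozygous	chr21	True	3.8	0.0855	1.4615	NA
P38	ZNF442	c.843A[2>1]	p.Arg282Aspfs*59	NM_030824.2	maternal	frameshift	heterozygous	chr19	True	3.5	0.0771	2.6689	NA
P48	EIF4G2	c.1299+2delT	NA	NM_001172705.1	de_novo	splice_donor	heterozygous	chr11	False	60.5	0.0268	not_estimable	Linked
P52	SEMA3F	c.2161G[2>1]	p.Gly721Alafs*10	NM_004186.3	maternal	frameshift	heterozygous	chr3	True	3.1	0.0338	not_estimable	NA
P52	TMEM63A	c.1578T[6>7]	p.Phe529Leufs*6	NM_014698.2	maternal	frameshift	heterozygous	chr1	True	3	0.0075	not_estimable	NA
P60	ADAM18	c.56-2A>G	NA	NM_014237.2	maternal	splice_acceptor	heterozygous	chr8	True	42.7	0.7096	1.3975	NA
P60	BICC1	c.482A[3>2]	p.Thr162Profs*24	NM_001080512.1	maternal	frameshift	heterozygous	chr10	True	4.9	0.0307	not_estimable	NA
P60	GSTM3	c.48+2T>G	NA	NM_000849.4	maternal	splice_donor	heterozygous	chr1	True	96	0.0220	5.0025	NA
P60	KRT10	c.1458_1459delCC	p.His487Argfs*93	NM_000421.3	de_novo	frameshift	heterozygous	chr17	NA	9.6	0.3695	1.8646	NA
P60	SPRR2F	c.218A>G	p.*73*	NM_001014450.1	maternal	stop_retained	heterozygous	chr1	True	2.2	0.0307	not_estimable	NA
P60	TMEM19	c.738_739insTAGACATTTTTGT	p.Asp247*	NM_018279.3	maternal	frameshift	heterozygous	chr12	True	7	0.2906	3.7321	NA
P62	ABCB8	c.516_517delTG	p.Glu173Valfs*54	NM_007188.3	maternal	frameshift	heterozygous	chr7	True	13.6	0.0268	not_estimable	NA
P62	ACTL8	c.761_771delTGGCTCCTGAG	p.Val254Aspfs*4	NM_030812.2	maternal	frameshift	heterozygous	chr1	True	23.6	0.0268	not_estimable	Linked
P62	ARMC4	c.393C[4>5]	p.Ile133Hisfs*8	NM_018076.2	maternal	frameshift	heterozygous	chr10	True	22	0.3036	3.7321	NA
P62	CDH19	c.2059C>T	p.Gln687*	NM_021153.3	maternal	nonsense	heterozygous	chr18	True	1.9	0.2834	3.7321	NA
P62	MICA	c.801G>A	p.Trp267*	NM_001177519.1	maternal	nonsense	heterozygous	chr6	True	24.6	0.2916	3.7321	NA
P62	PRRG4	c.605C>G	p.Ser202*	NM_024081.5	maternal	nonsense	heterozygous	chr11	True	1	0.0268	not_estimable	NA
P62	RPUSD4	c.651+1G>A	NA	NM_032795.2	maternal	splice_donor	heterozygous	chr11	True	7	0.0075	not_estimable	NA
P62	TRA2B	c.1A>G	p.0?	NM_004593.2	de_novo	start_codon_loss	heterozygous	chr3	True	38.4	0.0268	not_estimable	Linked
P62	ZNF221	c.1309C>T	p.Arg437*	NM_013359.2	maternal	nonsense	heterozygous	chr19	True	3.5	0.0268	not_estimable	NA
P98	C1orf87	c.887C>G	p.Ser296*	NM_152377.2	maternal	nonsense	heterozygous	chr1	True	1.2	1.0000	1.2411	NA
P98	GNPTAB	c.98C[2>1]	p.Ala34Profs*49	NM_024312.4	maternal	frameshift	heterozygous	chr12	True	7.4	0.0342	5.6087	NA
P98	MAGEC1	c.721dupT	p.Ser241Phefs*14	NM_005462.4	de_novo	frameshift	hemizygous	chrX	NA	23.5	0.7476	0.6761	NA
P98	OR5C1	c.527G[2>1]	p.Lys177Argfs*40	NM_001001923.1	maternal	frameshift	heterozygous	chr9	True	1	0.0512	7.4924	NA
P98	RNF224	c.1A>G	p.0?	NM_001190228.1	maternal	start_codon_loss	heterozygous	chr9	True	1.2	0.3003	3.7321	NA
P98	SELP	c.2394T[3>1]	p.Phe799Glnfs*5	NM_003005.3	maternal	frameshift	heterozygous	chr1	True	3.1	0.0268	not_estimable	NA
P117	CD109	c.3911+1G>T	NA	NM_133493.3	maternal	splice_donor	heterozygous	chr6	True	3.3	0.1300	3.7321	NA
P117	DDX11	c.577G[4>2]	p.Glu194Glyfs*11	NM_030653.3	maternal	frameshift	heterozygous	chr12	True	8.2	0.0072	not_estimable	NA
P117	IDE	c.1484G>A	p.Trp495*	NM_004969.3	maternal	nonsense	heterozygous	chr10	True	18.1	0.0268	not_estimable	Linked
P117	NALCN	c.4905+1G>C	NA	NM_052867.2	maternal	splice_donor	heterozygous	chr13	True	2	0.2895	3.7321	NA
P117	PLAC9	c.28G>T	p.Gly10*	NM_001012973.1	de_novo	nonsense	heterozygous	chr10	False	8.4	0.0268	not_estimable	NA
P117	POLD2	c.885+2T>C	NA	NM_006230.3	maternal	splice_donor	heterozygous	chr7	True	14.4	0.0268	not_estimable	NA
P117	VPS13C	c.10438C>T	p.Arg3480*	NM_020821.2	maternal	nonsense	heterozygous	chr15	True	8.7	1.0000	1.2411	NA
P124	FIBP	c.86-2A>C	NA	NM_198897.1	maternal	splice_acceptor	heterozygous	chr11	True	40.7	0.0077	not_estimable	Linked
P124	KIF20B	c.4180A[2>1]	p.Asn1394Thrfs*30	NM_016195.2	maternal	frameshift	heterozygous	chr10	True	10.2	1.0000	1.8631	NA
P124	LRRFIP1	c.1702A[6>7]	p.Glu570Argfs*11	NM_004735.3	maternal	frameshift	heterozygous	chr2	True	7.3	0.0074	not_estimable	NA
P124	LMF1	c.468C[2>1]	p.Leu157Serfs*57	NM_022773.2	maternal	frameshift	heterozygous	chr16	True	5.8	0.0497	7.4761	NA
P124	ZNF700	c.415dupT	p.Ser139Phefs*4	NM_144566.1	maternal	frameshift	heterozygous	chr19	True	17.3	0.2864	3.7321	NA
P130	BTBD1	c.655delA	p.Ile219Leufs*3	NM_025238.3	maternal	frameshift	heterozygous	chr15	True	NA	0.3061	0.0000	NA
P130	NUP37	c.239_245delGGAGCCC	p.Trp80*	NM_024057.2	maternal	frameshift	heterozygous	chr12	True	17.8	0.0286	not_estimable	Linked
P130	SLC35D2	c.47_48insG	p.Gly17Argfs*69	NM_007001.2	de_novo	frameshift	heterozygous	chr9	False	5.1	0.1423	7.4761	NA
P130	ULK4	c.1797G>A	p.Trp599*	NM_017886.2	maternal	nonsense	heterozygous	chr3	True	27.5	0.0018	not_estimable	Not Linked
P131	ACSF2	c.92G>A	p.Trp31*	NM_025149.4	maternal	nonsense	heterozygous	chr17	True	4.5	0.0308	not_estimable	NA
P131	ADAM8	c.1948+1G>A	NA	NM_001109.4	de_novo	splice_donor	heterozygous	chr10	False	2.3	0.5901	0.5310	NA
P131	CWF19L2	c.308A[7>8]	p.Asn105Lysfs*3	NM_152434.2	maternal	frameshift	heterozygous	chr11	True	9	0.2921	3.7321	NA
P131	DDX39B	c.736-1G>C	NA	NM_004640.6	de_novo	splice_acceptor	heterozygous	chr6	False	21.3	0.0004	7.6434	Linked
P131	GLIPR1L2	c.97_110delCTACTGCTACTGGG	p.Leu33Phefs*2	NM_001270396.1	maternal	frameshift	heterozygous	chr12	True	44	0.2826	3.7321	NA
P131	KIAA1549L	c.33_45delTCTCATAGGCATC	p.Gly14*	NM_012194.2	maternal	frameshift	heterozygous	chr11	True	1.3	0.2872	3.7321	NA
P131	PIGT	c.1034-1G>C	NA	NM_015937.5	maternal	splice_acceptor	heterozygous	chr20	True	34.5	0.0308	not_estimable	Linked
P131	PPP1R3C	c.145C>T	p.Arg49*	NM_005398.5	maternal	nonsense	heterozygous	chr10	True	2.2	0.0308	not_estimable	NA
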