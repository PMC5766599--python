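transcript_id	gene_id	symbol	log2fc	p_value	fdr	biotype	fdr_confirm
ENST00000464746	ENSG00000172016	REG3A	7.812	0.002	0.019	retained_intron	<0.001
ENST00000559321	ENSG00000259485	CTD-2147F2.1	7.719	<0.001	0.007	lincRNA	<0.001
ENST00000521586	ENSG00000253929	CASC21	7.449	0.005	0.015	lincRNA	<0.001
ENST00000436530	ENSG00000225680	AL163953.2	7.157	<0.001	0.019	lincRNA	<0.001
ENST00000413290	ENSG00000224099	AC064834.1	6.954	<0.001	0.015	lincRNA	<0.001
ENST00000514769	ENSG00000251026	RP11-138J23.1	6.55	0.002	0.037	lincRNA	<0.001
ENST00000451622	ENSG00000231172	AC007099.1	6.463	0.002	0.052	antisense	<0.001
ENST00000419196	ENSG00000230234	RP1-276N6.2	6.202	<0.001	0.081	lincRNA	<0.001
ENST00000513572	ENSG00000251095	RP11-115D19.1	6.201	0.001	0.019	antisense	<0.001
ENST00000476618	ENSG00000091436	pk	5.867	0.003	0.093	retained_intron	<0.001
ENST00000456880	ENSG00000230061	TRPM2-AS	5.677	0.003	0.092	antisense	<0.001
ENST00000560314	ENSG00000259485	CTD-2147F2.1	5.671	<0.001	0.093	lincRNA	<0.001
ENST00000521815	ENSG00000254166	CASC19	5.595	<0.001	0.051	lincRNA	<0.001
ENST00000532195	ENSG00000137699	TRIM29	5.541	0.002	0.11	retained_intron	0.018
ENST00000479258	ENSG00000172023	REG1B	5.526	0.002	0.128	retained_intron	<0.001
ENST00000510419	ENSG00000249942	AC142293.3	5.309	0.002	0.146	antisense	<0.001
ENST00000500112	ENSG00000247844	CCAT1	4.9	0.004	0.019	lincRNA	<0.001
ENST00000446246	ENSG00000235669	AC004593.3	4.326	0.001	0.151	antisense	<0.001
ENST00000531363	ENSG00000254560	BBOX 1-AS1	4.19	0.003	0.16	antisense	<0.001
ENST00000445083	ENSG00000225328	LINC01594	4.071	0.003	0.188	antisense	<0.001
ENST00000456253	ENSG00000228956	SATB1-AS1	4.044	0.001	0.166	antisense	0.007
ENST00000419422	ENSG00000232445	RP11-132A1.4	4.037	<0.001	0.091	antisense	<0.001
ENST00000415469	ENSG00000229404	LINC00858	3.708	<0.001	0.166	lincRNA	<0.001
ENST00000498352	ENSG00000090104	RGS1	3.646	0.003	0.155	retained_intron	<0.001
ENST00000397381	ENSG00000214049	UCA1	3.602	<0.001	0.146	lincRNA	<0.001
ENST00000433644	ENSG00000237857	RP11-435O5.2	3.354	<0.001	0.188	lincRNA	0.042
ENST00000377722	ENSG00000204876	AC021218.2	3.134	<0.001	0.192	lincRNA	<0.001
ENST00000497872	ENSG00000253701	AL928768.3	-3.205	0.002	0.146	lincRNA	<0.001
ENST00000522615	ENSG00000254042	CTC-558O2.1	-3.341	0.002	0.16	antisense	<0.001
ENST00000531791	ENSG00000162241	SLC25A45	-3.344	0.003	0.188	retained_intron	0.045
ENST00000488268	ENSG00000121310	ECHDC2	-3.354	0.004	0.18	retained_intron	0.002
ENST00000548722	ENSG00000257194	RP11-567C2.1	-3.448	0.004	0.188	lincRNA	<0.001
ENST00000452922	ENSG00000224081	LINC01057	-3.459	<0.001	0.166	lincRNA	<0.001
ENST00000524052	ENSG00000253549	CA3-AS1	-3.712	0.004	0.145	antisense	<0.001
ENST00000456403	ENSG00000226629	LINC00974	-3.771	0.002	0.143	lincRNA	<0.001
ENST00000428573	ENSG00000226862	RP11-569A11.1	-3.89	<0.001	0.151	antisense	0.005
ENST00000464125	ENSG00000244383	FAM3D-AS1	-4.097	<0.001	0.142	antisense	<0.001
ENST00000536094	ENSG00000251301	RP11-81H14.2	-4.101	<0.001	0.197	lincRNA	<0.001
ENST00000448587	ENSG00000223573	TINCR	-4.111	0.002	0.057	lincRNA	<0.001
ENST00000488733	ENSG00000163399	ATP1A1	-4.144	0.004	0.145	retained_intron	0.012
ENST00000463617	ENSG00000100417	PMM1	-4.152	0.003	0.185	retained_intron	0.004
ENST00000464150	ENSG00000186417	GLDN	-4.161	0.003	0.152	retained_intron	<0.001
ENST00000533203	ENSG00000255186	RP11-514F3.5	-4.199	<0.001	0.162	sense_intronic	<0.001
ENST00000559274	ENSG00000075413	MARK3	-4.243	<0.001	0.161	retained_intron	0.008
ENST00000529171	ENSG00000254718	CTD-2184C24.2	-4.351	0.003	0.168	antisense	<0.001
ENST00000433071	ENSG00000237594	AP000251.3	-4.826	<0.001	0.093	antisense	<0.001
ENST00000501708	ENSG00000245156	RP11-867G23.3	-4.883	0.004	0.087	lincRNA	0.021
ENST00000427901	ENSG00000235523	RP11-63P12.7	-5.119	<0.001	0.061	lincRNA	<0.001
ENST00000398460	ENSG00000214548	MEG3	-5.238	<0.001	0.151	lincRNA	<0.001
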