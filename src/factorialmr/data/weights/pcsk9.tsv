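variant_id	effect_allele	eaf	beta	trait
pcsk9_snp0000	A	0.7708	-0.355536	pcsk9
pcsk9_snp0001	G	0.9381	0.165279	pcsk9
pcsk9_snp0002	T	0.1156	-0.670981	pcsk9
pcsk9_snp0003	A	0.6083	0.164998	pcsk9
pcsk9_snp0004	A	0.5797	-0.58524	pcsk9
pcsk9_snp0005	G	0.2943	-0.123553	pcsk9
pcsk9_snp0006	T	0.3931	0.349197	pcsk9
pcsk9_snp0007	C	0.8553	-0.003041	pcsk9
pcsk9_snp0008	G	0.6881	-0.581144	pcsk9
pcsk9_snp0009	T	0.1557	0.423627	pcsk9
pcsk9_snp0010	T	0.7969	-0.452269	pcsk9
pcsk9_snp0011	G	0.4339	-0.821486	pcsk9
pcsk9_snp0012	A	0.2188	-0.160401	pcsk9
pcsk9_snp0013	G	0.5885	0.689459	pcsk9
pcsk9_snp0014	C	0.9448	-0.370566	pcsk9
pcsk9_snp0015	T	0.5994	-0.036659	pcsk9
pcsk9_snp0016	A	0.7973	0.120698	pcsk9
pcsk9_snp0017	C	0.6417	0.659325	pcsk9
pcsk9_snp0018	C	0.5199	-0.747108	pcsk9
pcsk9_snp0019	G	0.6807	0.053892	pcsk9
pcsk9_snp0020	G	0.5384	-0.566375	pcsk9
pcsk9_snp0021	T	0.4396	0.072277	pcsk9
pcsk9_snp0022	C	0.6931	0.519793	pcsk9
pcsk9_snp0023	T	0.2544	0.366272	pcsk9
pcsk9_snp0024	G	0.4976	-0.027524	pcsk9
pcsk9_snp0025	T	0.4298	0.032728	pcsk9
pcsk9_snp0026	C	0.6846	0.146552	pcsk9
pcsk9_snp0027	G	0.4137	-0.057851	pcsk9
pcsk9_snp0028	G	0.604	-0.118192	pcsk9
pcsk9_snp0029	G	0.1567	-0.054226	pcsk9
pcsk9_snp0030	T	0.4628	0.013149	pcsk9
pcsk9_snp0031	T	0.2959	-0.16416	pcsk9
pcsk9_snp0032	C	0.8108	1.075865	pcsk9
pcsk9_snp0033	A	0.1312	0.25983	pcsk9
pcsk9_snp0034	T	0.2864	-0.46794	pcsk9
pcsk9_snp0035	T	0.8791	-0.101711	pcsk9
pcsk9_snp0036	A	0.6665	0.521689	pcsk9
pcsk9_snp0037	T	0.8336	0.118212	pcsk9
pcsk9_snp0038	T	0.8118	-0.217119	pcsk9
pcsk9_snp0039	T	0.7105	-0.429859	pcsk9
pcsk9_snp0040	C	0.8512	0.422104	pcsk9
pcsk9_snp0041	C	0.478	0.372167	pcsk9
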