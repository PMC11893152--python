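variant_id	effect_allele	eaf	beta	trait
lpa_snp0000	C	0.3652	-7.549553	lpa
lpa_snp0001	C	0.7562	2.181133	lpa
lpa_snp0002	C	0.5129	-0.949632	lpa
lpa_snp0003	G	0.131	-0.79183	lpa
lpa_snp0004	A	0.0508	-1.689828	lpa
lpa_snp0005	A	0.5355	0.410317	lpa
lpa_snp0006	A	0.3768	5.312353	lpa
lpa_snp0007	C	0.6405	-0.931211	lpa
lpa_snp0008	C	0.6672	-2.790931	lpa
lpa_snp0009	G	0.309	-2.939847	lpa
lpa_snp0010	G	0.3376	-0.507781	lpa
lpa_snp0011	A	0.5136	-3.984577	lpa
lpa_snp0012	A	0.6541	-0.200768	lpa
lpa_snp0013	G	0.2205	-3.829884	lpa
lpa_snp0014	T	0.7716	-2.640625	lpa
lpa_snp0015	C	0.3162	3.823507	lpa
lpa_snp0016	T	0.3077	3.572569	lpa
lpa_snp0017	G	0.8903	-0.473623	lpa
lpa_snp0018	G	0.8581	1.105063	lpa
lpa_snp0019	A	0.3406	-6.959242	lpa
lpa_snp0020	C	0.4508	1.160346	lpa
lpa_snp0021	A	0.2361	0.409604	lpa
lpa_snp0022	G	0.1838	4.575591	lpa
lpa_snp0023	C	0.1129	1.172538	lpa
lpa_snp0024	G	0.7344	-0.233727	lpa
lpa_snp0025	A	0.9296	0.936072	lpa
lpa_snp0026	G	0.5449	3.293624	lpa
lpa_snp0027	A	0.2193	-3.271742	lpa
lpa_snp0028	A	0.4841	5.049572	lpa
lpa_snp0029	T	0.8799	-3.067175	lpa
lpa_snp0030	T	0.2492	1.410928	lpa
lpa_snp0031	G	0.3153	-1.956898	lpa
lpa_snp0032	T	0.4356	1.031391	lpa
lpa_snp0033	A	0.0863	1.455159	lpa
lpa_snp0034	G	0.2792	1.830784	lpa
lpa_snp0035	G	0.8542	2.374699	lpa
lpa_snp0036	C	0.6326	-0.475247	lpa
lpa_snp0037	T	0.0737	-3.059646	lpa
lpa_snp0038	C	0.4449	1.551576	lpa
lpa_snp0039	G	0.4688	-1.797133	lpa
lpa_snp0040	G	0.3101	-2.946444	lpa
lpa_snp0041	T	0.5751	-2.831618	lpa
lpa_snp0042	G	0.1245	4.09652	lpa
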