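variant_id	effect_allele	eaf	beta	trait
bmi_snp0000	T	0.7757	-0.064506	bmi
bmi_snp0001	G	0.7523	-0.200383	bmi
bmi_snp0002	C	0.1126	-0.091264	bmi
bmi_snp0003	C	0.4563	-0.071403	bmi
bmi_snp0004	C	0.2474	-0.065512	bmi
bmi_snp0005	G	0.4305	0.345007	bmi
bmi_snp0006	A	0.6884	-0.588166	bmi
bmi_snp0007	T	0.7423	-0.114009	bmi
bmi_snp0008	T	0.7092	-0.048142	bmi
bmi_snp0009	G	0.5952	-0.201728	bmi
bmi_snp0010	A	0.5568	0.009463	bmi
bmi_snp0011	C	0.3798	0.337375	bmi
bmi_snp0012	C	0.1555	-0.132363	bmi
bmi_snp0013	G	0.9487	-0.013103	bmi
bmi_snp0014	A	0.3816	0.184182	bmi
bmi_snp0015	A	0.4302	-0.042029	bmi
bmi_snp0016	T	0.7973	0.079663	bmi
bmi_snp0017	C	0.7623	0.180821	bmi
bmi_snp0018	G	0.8857	0.010923	bmi
bmi_snp0019	G	0.5226	0.306954	bmi
bmi_snp0020	G	0.1324	0.199871	bmi
bmi_snp0021	C	0.9109	-0.158541	bmi
bmi_snp0022	A	0.458	-0.044196	bmi
bmi_snp0023	A	0.732	-0.088695	bmi
bmi_snp0024	C	0.6187	0.231139	bmi
bmi_snp0025	A	0.684	0.15979	bmi
bmi_snp0026	T	0.516	0.025596	bmi
bmi_snp0027	G	0.9244	0.05573	bmi
bmi_snp0028	A	0.1215	0.162012	bmi
bmi_snp0029	C	0.1753	0.009216	bmi
bmi_snp0030	G	0.215	0.081759	bmi
bmi_snp0031	T	0.4571	0.239367	bmi
bmi_snp0032	C	0.1029	-0.295536	bmi
bmi_snp0033	C	0.3665	-0.091761	bmi
bmi_snp0034	A	0.4202	-0.193514	bmi
bmi_snp0035	C	0.784	-0.063647	bmi
bmi_snp0036	C	0.3255	0.193078	bmi
bmi_snp0037	C	0.8301	0.323153	bmi
bmi_snp0038	G	0.4784	0.061905	bmi
bmi_snp0039	C	0.7	-0.087476	bmi
bmi_snp0040	G	0.284	-0.22555	bmi
bmi_snp0041	C	0.229	0.215621	bmi
bmi_snp0042	T	0.5059	0.016804	bmi
bmi_snp0043	C	0.8063	-0.244404	bmi
bmi_snp0044	C	0.3912	-0.074832	bmi
bmi_snp0045	C	0.9275	-0.05687	bmi
bmi_snp0046	C	0.5957	0.229016	bmi
bmi_snp0047	G	0.1795	0.026609	bmi
bmi_snp0048	C	0.8324	0.028478	bmi
bmi_snp0049	A	0.5186	-0.132237	bmi
bmi_snp0050	T	0.2837	-0.208418	bmi
bmi_snp0051	C	0.4097	-0.109155	bmi
bmi_snp0052	G	0.365	0.231717	bmi
bmi_snp0053	C	0.3017	-0.005096	bmi
bmi_snp0054	C	0.7769	0.147558	bmi
bmi_snp0055	A	0.4118	0.038714	bmi
bmi_snp0056	T	0.302	0.339325	bmi
bmi_snp0057	G	0.9443	0.062533	bmi
bmi_snp0058	A	0.7137	-0.05685	bmi
bmi_snp0059	G	0.7153	-0.12263	bmi
bmi_snp0060	A	0.6358	0.259272	bmi
bmi_snp0061	C	0.3272	0.03521	bmi
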