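variant_id	effect_allele	eaf	beta	trait
activity_snp0000	C	0.4356	-0.08236	activity
activity_snp0001	C	0.9492	-0.092086	activity
activity_snp0002	G	0.3414	-0.011308	activity
activity_snp0003	C	0.7215	0.17699	activity
activity_snp0004	G	0.5739	-0.105208	activity
activity_snp0005	T	0.1264	0.096004	activity
activity_snp0006	A	0.2077	0.051006	activity
activity_snp0007	T	0.6048	0.122259	activity
activity_snp0008	A	0.9287	0.025571	activity
activity_snp0009	G	0.448	0.00829	activity
activity_snp0010	C	0.6332	0.058804	activity
activity_snp0011	G	0.0699	0.078461	activity
activity_snp0012	C	0.5489	0.011281	activity
activity_snp0013	T	0.8899	0.027595	activity
activity_snp0014	C	0.3625	0.090849	activity
activity_snp0015	G	0.2173	0.059268	activity
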