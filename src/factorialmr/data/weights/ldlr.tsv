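variant_id	effect_allele	eaf	beta	trait
ldlr_snp0000	G	0.6827	0.873343	ldlr
ldlr_snp0001	T	0.2295	0.108608	ldlr
ldlr_snp0002	G	0.2977	0.371373	ldlr
ldlr_snp0003	T	0.1061	1.425242	ldlr
ldlr_snp0004	A	0.3219	-0.127299	ldlr
ldlr_snp0005	G	0.8847	-0.005431	ldlr
ldlr_snp0006	C	0.7693	-0.074714	ldlr
ldlr_snp0007	G	0.9224	-0.204878	ldlr
ldlr_snp0008	G	0.4073	-0.878615	ldlr
ldlr_snp0009	C	0.4093	-0.082045	ldlr
ldlr_snp0010	A	0.5206	0.160277	ldlr
ldlr_snp0011	A	0.7474	0.238684	ldlr
ldlr_snp0012	A	0.0516	-1.079991	ldlr
ldlr_snp0013	T	0.7976	-0.339049	ldlr
ldlr_snp0014	T	0.4558	-0.503995	ldlr
ldlr_snp0015	T	0.7517	0.642496	ldlr
ldlr_snp0016	A	0.1727	-1.011756	ldlr
ldlr_snp0017	A	0.4999	0.88125	ldlr
ldlr_snp0018	A	0.7259	-0.330887	ldlr
ldlr_snp0019	C	0.6356	-0.695003	ldlr
ldlr_snp0020	A	0.1887	-0.367501	ldlr
ldlr_snp0021	A	0.2365	-0.084869	ldlr
ldlr_snp0022	G	0.5217	-0.985801	ldlr
ldlr_snp0023	T	0.7446	0.077355	ldlr
ldlr_snp0024	C	0.4954	-0.482432	ldlr
ldlr_snp0025	C	0.1728	-0.190969	ldlr
ldlr_snp0026	C	0.5981	0.955469	ldlr
ldlr_snp0027	T	0.4023	-0.292569	ldlr
ldlr_snp0028	T	0.2282	-0.090432	ldlr
ldlr_snp0029	C	0.5092	0.17761	ldlr
ldlr_snp0030	G	0.9083	-0.367228	ldlr
ldlr_snp0031	C	0.8586	-0.266144	ldlr
ldlr_snp0032	A	0.5869	1.049094	ldlr
ldlr_snp0033	T	0.2332	-0.960374	ldlr
ldlr_snp0034	A	0.1463	0.215038	ldlr
ldlr_snp0035	T	0.3167	-0.985811	ldlr
ldlr_snp0036	T	0.2943	-0.476524	ldlr
ldlr_snp0037	T	0.4828	-0.715711	ldlr
ldlr_snp0038	A	0.9137	0.2521	ldlr
ldlr_snp0039	T	0.3833	-0.034786	ldlr
ldlr_snp0040	T	0.2411	-0.356951	ldlr
ldlr_snp0041	G	0.3898	-0.184582	ldlr
ldlr_snp0042	A	0.5098	-0.334829	ldlr
ldlr_snp0043	A	0.0607	-0.62485	ldlr
ldlr_snp0044	C	0.1652	-0.03236	ldlr
ldlr_snp0045	G	0.615	0.275986	ldlr
ldlr_snp0046	G	0.7957	-0.459635	ldlr
ldlr_snp0047	A	0.9044	0.083148	ldlr
ldlr_snp0048	G	0.1271	0.480054	ldlr
ldlr_snp0049	A	0.7961	0.13448	ldlr
ldlr_snp0050	G	0.1702	0.322404	ldlr
ldlr_snp0051	G	0.2655	0.39314	ldlr
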