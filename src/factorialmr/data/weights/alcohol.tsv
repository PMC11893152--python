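variant_id	effect_allele	eaf	beta	trait
alcohol_snp0000	G	0.5664	0.022631	alcohol
alcohol_snp0001	C	0.4192	-0.092613	alcohol
alcohol_snp0002	G	0.1675	0.060659	alcohol
alcohol_snp0003	A	0.927	-0.031088	alcohol
alcohol_snp0004	A	0.3312	0.043202	alcohol
alcohol_snp0005	T	0.1295	0.000517	alcohol
alcohol_snp0006	A	0.8588	-0.065324	alcohol
alcohol_snp0007	G	0.913	0.044149	alcohol
alcohol_snp0008	A	0.1418	-0.109556	alcohol
alcohol_snp0009	T	0.0998	-0.058401	alcohol
alcohol_snp0010	C	0.6211	-0.04964	alcohol
alcohol_snp0011	C	0.2157	0.047511	alcohol
alcohol_snp0012	A	0.1519	-0.039486	alcohol
alcohol_snp0013	A	0.2283	0.000481	alcohol
alcohol_snp0014	C	0.0889	-0.020791	alcohol
alcohol_snp0015	C	0.3917	-0.012201	alcohol
alcohol_snp0016	T	0.8154	0.000503	alcohol
alcohol_snp0017	A	0.3863	-0.066451	alcohol
alcohol_snp0018	C	0.386	0.018862	alcohol
alcohol_snp0019	A	0.6436	-0.009506	alcohol
alcohol_snp0020	G	0.1335	-0.028664	alcohol
alcohol_snp0021	A	0.0884	0.029621	alcohol
alcohol_snp0022	G	0.571	-0.03561	alcohol
alcohol_snp0023	T	0.2772	0.01885	alcohol
alcohol_snp0024	G	0.9084	0.003616	alcohol
alcohol_snp0025	C	0.099	-0.074318	alcohol
alcohol_snp0026	A	0.7721	0.004057	alcohol
alcohol_snp0027	C	0.3061	-0.039471	alcohol
alcohol_snp0028	C	0.4538	0.017997	alcohol
alcohol_snp0029	T	0.7866	0.092089	alcohol
alcohol_snp0030	C	0.103	-0.028203	alcohol
alcohol_snp0031	A	0.7176	-0.033795	alcohol
alcohol_snp0032	T	0.5789	0.030324	alcohol
alcohol_snp0033	A	0.4151	-0.022208	alcohol
alcohol_snp0034	A	0.3906	0.041042	alcohol
alcohol_snp0035	T	0.5879	0.028254	alcohol
alcohol_snp0036	G	0.9026	-0.102757	alcohol
alcohol_snp0037	C	0.6668	-0.013422	alcohol
alcohol_snp0038	A	0.4987	0.018244	alcohol
alcohol_snp0039	T	0.4558	-0.001963	alcohol
alcohol_snp0040	C	0.6844	-0.040286	alcohol
alcohol_snp0041	C	0.4415	0.009989	alcohol
alcohol_snp0042	G	0.6068	0.034638	alcohol
alcohol_snp0043	T	0.4581	0.002972	alcohol
alcohol_snp0044	A	0.3907	-0.010095	alcohol
alcohol_snp0045	A	0.0602	0.00687	alcohol
alcohol_snp0046	T	0.0746	-0.018709	alcohol
alcohol_snp0047	G	0.0998	-0.021182	alcohol
alcohol_snp0048	T	0.6398	-0.026313	alcohol
alcohol_snp0049	T	0.4812	-0.001481	alcohol
alcohol_snp0050	G	0.1305	-0.013353	alcohol
alcohol_snp0051	T	0.8213	-0.02971	alcohol
alcohol_snp0052	G	0.6107	-0.001912	alcohol
alcohol_snp0053	A	0.4584	0.044705	alcohol
alcohol_snp0054	A	0.7805	0.109105	alcohol
alcohol_snp0055	T	0.8046	0.010878	alcohol
alcohol_snp0056	G	0.1858	0.028804	alcohol
alcohol_snp0057	G	0.1074	0.055653	alcohol
alcohol_snp0058	G	0.9444	0.095414	alcohol
alcohol_snp0059	C	0.558	-0.063744	alcohol
alcohol_snp0060	A	0.2109	-0.026068	alcohol
alcohol_snp0061	G	0.915	-0.003416	alcohol
alcohol_snp0062	C	0.6203	0.098058	alcohol
alcohol_snp0063	G	0.4838	0.024963	alcohol
alcohol_snp0064	A	0.232	0.032837	alcohol
alcohol_snp0065	A	0.5529	-0.001318	alcohol
alcohol_snp0066	C	0.8211	0.122584	alcohol
alcohol_snp0067	T	0.2071	0.037155	alcohol
alcohol_snp0068	A	0.9116	-0.059278	alcohol
alcohol_snp0069	C	0.2033	-0.057949	alcohol
alcohol_snp0070	A	0.3636	0.003705	alcohol
alcohol_snp0071	G	0.6482	0.026067	alcohol
alcohol_snp0072	G	0.5501	-0.11708	alcohol
alcohol_snp0073	A	0.1175	0.102507	alcohol
alcohol_snp0074	G	0.7399	-0.039075	alcohol
alcohol_snp0075	A	0.4405	0.060862	alcohol
alcohol_snp0076	G	0.3952	0.092192	alcohol
alcohol_snp0077	G	0.7703	0.082859	alcohol
alcohol_snp0078	A	0.2752	-0.023466	alcohol
alcohol_snp0079	T	0.7702	-0.055039	alcohol
alcohol_snp0080	G	0.598	0.06996	alcohol
alcohol_snp0081	G	0.8703	0.052603	alcohol
alcohol_snp0082	G	0.9226	0.057282	alcohol
alcohol_snp0083	A	0.2583	0.00946	alcohol
alcohol_snp0084	G	0.8891	-0.038062	alcohol
alcohol_snp0085	A	0.4435	0.052509	alcohol
alcohol_snp0086	C	0.7153	0.043013	alcohol
alcohol_snp0087	T	0.2309	0.011925	alcohol
alcohol_snp0088	T	0.8574	-0.085918	alcohol
alcohol_snp0089	G	0.9247	0.032576	alcohol
alcohol_snp0090	C	0.6215	0.121679	alcohol
alcohol_snp0091	C	0.4637	-0.077781	alcohol
alcohol_snp0092	A	0.5726	0.011745	alcohol
alcohol_snp0093	A	0.5458	0.010719	alcohol
alcohol_snp0094	A	0.4604	0.052943	alcohol
alcohol_snp0095	C	0.0561	0.005878	alcohol
alcohol_snp0096	G	0.1543	0.068144	alcohol
alcohol_snp0097	T	0.0833	-0.057008	alcohol
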