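variant_id	effect_allele	eaf	beta	trait
hmgcr_snp0000	T	0.6227	-0.711002	hmgcr
hmgcr_snp0001	G	0.1864	-0.241642	hmgcr
hmgcr_snp0002	A	0.8537	-0.114256	hmgcr
hmgcr_snp0003	T	0.8399	-0.127089	hmgcr
hmgcr_snp0004	C	0.4837	0.079899	hmgcr
hmgcr_snp0005	G	0.6296	-0.867559	hmgcr
hmgcr_snp0006	C	0.8956	-0.191581	hmgcr
hmgcr_snp0007	G	0.1428	0.307717	hmgcr
hmgcr_snp0008	G	0.4866	-0.051442	hmgcr
hmgcr_snp0009	A	0.1435	0.831447	hmgcr
hmgcr_snp0010	G	0.8374	-0.049658	hmgcr
hmgcr_snp0011	G	0.2147	-0.04035	hmgcr
hmgcr_snp0012	C	0.4007	-0.108581	hmgcr
hmgcr_snp0013	A	0.2504	-0.003835	hmgcr
hmgcr_snp0014	G	0.1648	0.409574	hmgcr
hmgcr_snp0015	G	0.4833	-0.698301	hmgcr
hmgcr_snp0016	C	0.5881	-1.173618	hmgcr
hmgcr_snp0017	T	0.9163	-0.204863	hmgcr
hmgcr_snp0018	C	0.3193	0.394832	hmgcr
hmgcr_snp0019	A	0.3662	0.657737	hmgcr
hmgcr_snp0020	G	0.277	-0.823172	hmgcr
hmgcr_snp0021	A	0.5795	-0.072383	hmgcr
hmgcr_snp0022	G	0.2928	0.155642	hmgcr
hmgcr_snp0023	G	0.4012	0.30434	hmgcr
hmgcr_snp0024	T	0.4898	-0.360318	hmgcr
hmgcr_snp0025	C	0.9052	-0.097849	hmgcr
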