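variant_id	effect_allele	eaf	beta	trait
npc1l1_snp0000	A	0.3756	0.017376	npc1l1
npc1l1_snp0001	C	0.5779	-0.582343	npc1l1
npc1l1_snp0002	C	0.3308	-0.090525	npc1l1
npc1l1_snp0003	A	0.6951	0.192721	npc1l1
npc1l1_snp0004	T	0.5972	-0.617879	npc1l1
npc1l1_snp0005	T	0.1617	0.516376	npc1l1
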