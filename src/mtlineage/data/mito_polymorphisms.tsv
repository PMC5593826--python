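# Packaged snapshot of known mitochondrial polymorphisms (no network access at run time).
# Sources are database snapshots: MITOMAP, dbSNP (v138) and HAPMAP (phase 3).
# disease_flag = 1 marks sites reported as disease-associated in MITOMAP.
# snapshot_version: 2017-frozen
position	ref	alt	source	disease_flag	note
73	A	G	dbSNP	0	control region HV2 polymorphism
146	T	C	dbSNP	0	control region polymorphism
263	A	G	MITOMAP	0	near-universal HV2 polymorphism
489	T	C	MITOMAP	0	control region polymorphism
750	A	G	MITOMAP	0	12S rRNA polymorphism
1438	A	G	MITOMAP	0	12S rRNA polymorphism
2706	A	G	HAPMAP	0	16S rRNA polymorphism
3010	G	A	MITOMAP	0	16S rRNA polymorphism
4769	A	G	MITOMAP	0	ND2 synonymous polymorphism
7028	C	T	MITOMAP	0	CO1 haplogroup H marker
8860	A	G	MITOMAP	0	ATP6 polymorphism
9540	T	C	HAPMAP	0	CO3 polymorphism
10398	A	G	MITOMAP	1	ND3; associated with breast and endometrial cancer risk
10873	T	C	HAPMAP	0	ND4 polymorphism
11719	G	A	dbSNP	0	ND4 polymorphism
12705	C	T	dbSNP	0	ND5 polymorphism
14766	C	T	MITOMAP	0	CYB polymorphism
15326	A	G	MITOMAP	0	CYB polymorphism
16189	T	C	MITOMAP	1	hypermutable polyC stretch; cancer-risk associated
16519	T	C	dbSNP	0	control region polymorphism
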