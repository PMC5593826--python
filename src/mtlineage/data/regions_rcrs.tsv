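# Region annotation for the 16,569 bp human mitochondrial map (rCRS, NC_012920).
# Coordinates are 1-based inclusive; start > end wraps through the origin.
# Gene coordinates follow the standard MITOMAP/RefSeq annotation of NC_012920.
# 37 genes (13 protein-coding, 2 rRNA, 22 tRNA) + control region + 2 microsatellites.
label	start	end	category
TF	577	647	tRNA
RNR1	648	1601	rRNA
TV	1602	1670	tRNA
RNR2	1671	3229	rRNA
TL1	3230	3304	tRNA
ND1	3307	4262	protein_gene
TI	4263	4331	tRNA
TQ	4329	4400	tRNA
TM	4402	4469	tRNA
ND2	4470	5511	protein_gene
TW	5512	5579	tRNA
TA	5587	5655	tRNA
TN	5657	5729	tRNA
TC	5761	5826	tRNA
TY	5826	5891	tRNA
CO1	5904	7445	protein_gene
TS1	7446	7514	tRNA
TD	7518	7585	tRNA
CO2	7586	8269	protein_gene
TK	8295	8364	tRNA
ATP8	8366	8572	protein_gene
ATP6	8527	9207	protein_gene
CO3	9207	9990	protein_gene
TG	9991	10058	tRNA
ND3	10059	10404	protein_gene
TR	10405	10469	tRNA
ND4L	10470	10766	protein_gene
ND4	10760	12137	protein_gene
TH	12138	12206	tRNA
TS2	12207	12265	tRNA
TL2	12266	12336	tRNA
ND5	12337	14148	protein_gene
ND6	14149	14673	protein_gene
TE	14674	14742	tRNA
CYB	14747	15887	protein_gene
TT	15888	15953	tRNA
TP	15956	16023	tRNA
D-LOOP	16024	576	control_region
polyC 302-315	302	315	microsatellite
polyC 16184-16193	16184	16193	microsatellite
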