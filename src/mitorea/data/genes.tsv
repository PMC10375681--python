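name	start	end	feature_class
D-loop	16024	16569	control_region
D-loop	1	576	control_region
TF	577	647	tRNA
RNR1	648	1601	rRNA
TV	1602	1670	tRNA
RNR2	1671	3229	rRNA
TL1	3230	3304	tRNA
ND1	3307	4262	protein_coding
TI	4263	4331	tRNA
TQ	4329	4400	tRNA
TM	4402	4469	tRNA
ND2	4470	5511	protein_coding
TW	5512	5579	tRNA
TA	5587	5655	tRNA
TN	5657	5729	tRNA
TC	5761	5826	tRNA
TY	5826	5891	tRNA
COI	5904	7445	protein_coding
TS1	7446	7514	tRNA
TD	7518	7585	tRNA
COII	7586	8269	protein_coding
TK	8295	8364	tRNA
ATP8	8366	8572	protein_coding
ATP6	8527	9207	protein_coding
COIII	9207	9990	protein_coding
TG	9991	10058	tRNA
ND3	10059	10404	protein_coding
TR	10405	10469	tRNA
ND4L	10470	10766	protein_coding
ND4	10760	12137	protein_coding
TH	12138	12206	tRNA
TS2	12207	12265	tRNA
TL2	12266	12336	tRNA
ND5	12337	14148	protein_coding
ND6	14149	14673	protein_coding
TE	14674	14742	tRNA
CYB	14747	15887	protein_coding
TT	15888	15953	tRNA
TP	15956	16023	tRNA
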