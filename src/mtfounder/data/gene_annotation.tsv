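# human mtDNA gene coordinates, 1-based inclusive
RNR1	648	1601	+	0	rRNA
RNR2	1671	3229	+	0	rRNA
ND1	3307	4262	+	0	protein
ND2	4470	5511	+	0	protein
CO1	5904	7445	+	0	protein
CO2	7586	8269	+	0	protein
ATP8	8366	8572	+	0	protein
ATP6	8527	9207	+	0	protein
CO3	9207	9990	+	0	protein
ND3	10059	10404	+	0	protein
ND4L	10470	10766	+	0	protein
ND4	10760	12137	+	0	protein
ND5	12337	14148	+	0	protein
ND6	14149	14673	-	0	protein
CYTB	14747	15887	+	0	protein
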