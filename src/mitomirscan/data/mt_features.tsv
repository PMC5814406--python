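# Human mitochondrial genome feature map, standard rCRS (NC_012920) annotation coordinates.
# 1-based inclusive; start > end means the feature wraps the sequence origin.
# Columns: name, class, start, end, strand, description
# strand: L = sense on the printed (light, C-rich) reference strand; H = heavy-strand sense.
# Hypervariable-region boundaries: HVR1 16024-16383, HVR2 57-372, HVR3 438-574; the control
# region is modelled as one origin-wrapping feature 16024..576 (D-loop annotation).
name	class	start	end	strand	description
MT-CR	non_coding	16024	576	L	control region (D-loop), longest non coding sequence
MT-HVR1	non_coding	16024	16383	L	hypervariable region I
MT-HVR2	non_coding	57	372	L	hypervariable region II
MT-HVR3	non_coding	438	574	L	hypervariable region III
MT-TF	tRNA	577	647	L	tRNA-Phe
MT-RNR1	rRNA	648	1601	L	12 S ribosomal RNA
MT-TV	tRNA	1602	1670	L	tRNA-Val
MT-RNR2	rRNA	1671	3229	L	16 S ribosomal RNA
MT-TL1	tRNA	3230	3304	L	tRNA-LeuUUR
MT-ND1	protein_coding	3307	4262	L	subunit ND1 of complex I (NADH dehydrogenase)
MT-TI	tRNA	4263	4331	L	tRNA-Ile
MT-TQ	tRNA	4329	4400	H	tRNA-Gln
MT-TM	tRNA	4402	4469	L	tRNA-Met
MT-ND2	protein_coding	4470	5511	L	subunit ND2 of complex I (NADH dehydrogenase)
MT-TW	tRNA	5512	5579	L	tRNA-Trp
MT-TA	tRNA	5587	5655	H	tRNA-Ala
MT-TN	tRNA	5657	5729	H	tRNA-Asn
MT-TC	tRNA	5761	5826	H	tRNA-Cys
MT-TY	tRNA	5826	5891	H	tRNA-Tyr
MT-CO1	protein_coding	5904	7445	L	subunit COI of complex IV (cytochrome c oxidase)
MT-TS1	tRNA	7446	7514	H	tRNA-SerUCN
MT-TD	tRNA	7518	7585	L	tRNA-Asp
MT-CO2	protein_coding	7586	8269	L	subunit COII of complex IV (cytochrome c oxidase)
MT-TK	tRNA	8295	8364	L	tRNA-Lys
MT-ATP8	protein_coding	8366	8572	L	subunit ATP8 of complex V (ATP synthase)
MT-ATP6	protein_coding	8527	9207	L	subunit ATP6 of complex V (ATP synthase)
MT-CO3	protein_coding	9207	9990	L	subunit COIII of complex IV (cytochrome c oxidase)
MT-TG	tRNA	9991	10058	L	tRNA-Gly
MT-ND3	protein_coding	10059	10404	L	subunit ND3 of complex I (NADH dehydrogenase)
MT-TR	tRNA	10405	10469	L	tRNA-Arg
MT-ND4L	protein_coding	10470	10766	L	subunit ND4L of complex I (NADH dehydrogenase)
MT-ND4	protein_coding	10760	12137	L	subunit ND4 of complex I (NADH dehydrogenase)
MT-TH	tRNA	12138	12206	L	tRNA-His
MT-TS2	tRNA	12207	12265	L	tRNA-SerAGY
MT-TL2	tRNA	12266	12336	L	tRNA-LeuCUN
MT-ND5	protein_coding	12337	14148	L	subunit ND5 of complex I (NADH dehydrogenase)
MT-ND6	protein_coding	14149	14673	H	subunit ND6 of complex I (NADH dehydrogenase)
MT-TE	tRNA	14674	14742	H	tRNA-Glu
MT-CYB	protein_coding	14747	15887	L	cytochrome b subunit of C3 (ubiquinol:cytochrome c oxidoreductase)
MT-TT	tRNA	15888	15953	L	tRNA-Thr
MT-TP	tRNA	15956	16023	H	tRNA-Pro
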