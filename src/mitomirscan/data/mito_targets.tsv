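# Nuclear-encoded mitochondrial ORF targets of the liver-PNF miRNAs: miRDB prediction score
# (50-100), MitoMiner IMPI mitochondrial-localization score, and ORF length in nucleotides.
# A gene targeted by several miRNAs lists them semicolon-separated in mirna_id (first = primary).
# Columns: mirna_id, gene_id, symbol, target_score, impi, orf_length_nt
mirna_id	gene_id	symbol	target_score	impi	orf_length_nt
miR-107;miR-103a-3p	ENSG00000164898	C7orf55	61	1	342
miR-23b	ENSG00000164241	C5orf63	64	0.8	417
miR-23b	ENSG00000178074	C2orf69	99	0.72	1158
miR-23b	ENSG00000169609	C15orf40	55	0.79	462
miR-194-5p	ENSG00000133943	C14orf159	61	1	1851
miR-296-3p	ENSG00000213563	C8orf82	69	0.72	651
miR-940	ENSG00000131943	C19orf12	72	1	459
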